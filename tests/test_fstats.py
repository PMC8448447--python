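"""f3/f4 estimates, jackknife errors, Haversine distances, drift regression."""

import math

import numpy as np
import pytest

from rohabc.fstats import (
    FreqTable,
    GeoRecord,
    block_jackknife,
    drift_distance_test,
    f4,
    haversine_km,
    outgroup_f3,
)


def freq_table(n_sites, rng=None, block_bp=5_000_000, pops=("O", "A", "B", "C", "D")):
    rng = rng or np.random.default_rng(0)
    pos = np.arange(n_sites) * 100_000 + 1
    return FreqTable(
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos=pos,
        freqs={p: rng.random(n_sites) for p in pops},
    )


class TestF3:
    def test_fixed_difference_gives_one(self):
        n = 200
        t = FreqTable(
            chrom=np.full(n, "chr1", dtype=object),
            pos=np.arange(n) * 100_000 + 1,
            freqs={"O": np.zeros(n), "A": np.ones(n), "B": np.ones(n)},
        )
        res = outgroup_f3(t, "O", "A", "B")
        assert res.estimate == 1.0

    def test_null_case_within_three_se(self, rng):
        """A and B drawn from the outgroup's frequencies: f3 ~ 0."""
        n = 5000
        o = rng.uniform(0.05, 0.95, n)
        noise = lambda: np.clip(o + rng.normal(0, 0.05, n), 0, 1)
        t = FreqTable(
            chrom=np.full(n, "chr1", dtype=object),
            pos=np.arange(n) * 50_000 + 1,
            freqs={"O": o, "A": noise(), "B": noise()},
        )
        res = outgroup_f3(t, "O", "A", "B")
        assert abs(res.estimate) <= 3 * res.jackknife_se

    def test_symmetry_in_A_B(self, rng):
        t = freq_table(400, rng)
        a = outgroup_f3(t, "O", "A", "B")
        b = outgroup_f3(t, "O", "B", "A")
        assert a.estimate == b.estimate and a.jackknife_se == b.jackknife_se

    def test_estimate_is_unblocked_mean_and_2block_se_matches_hand_formula(self, rng):
        """On a 2-equal-block toy table the weighted jackknife reduces to
        SE = |mean(block1) - mean(block2)| / 2."""
        n = 100  # two 5-Mb blocks of 50 sites at 100-kb spacing
        t = freq_table(n, rng, pops=("O", "A", "B"))
        res = outgroup_f3(t, "O", "A", "B", block_size_bp=5_000_000)
        v = (t.freqs["O"] - t.freqs["A"]) * (t.freqs["O"] - t.freqs["B"])
        assert res.estimate == pytest.approx(v.mean(), abs=1e-15)
        assert res.n_blocks == 2
        hand_se = abs(v[:50].mean() - v[50:].mean()) / 2
        assert res.jackknife_se == pytest.approx(hand_se, rel=1e-12)
        assert res.z == pytest.approx(res.estimate / res.jackknife_se, abs=1e-12)

    def test_missing_population_rejected(self, rng):
        with pytest.raises(KeyError):
            outgroup_f3(freq_table(100, rng), "O", "A", "Z")

    def test_single_block_rejected(self, rng):
        t = freq_table(10, rng)  # 10 sites in one 5-Mb block
        t.pos = np.arange(10) * 100 + 1
        with pytest.raises(ValueError, match="blocks"):
            outgroup_f3(t, "O", "A", "B")


class TestF4:
    def test_duplicated_population_gives_exact_zero(self, rng):
        res = f4(freq_table(300, rng), "A", "B", "C", "C")
        assert res.estimate == 0.0

    def test_fixed_differences_give_one(self):
        n = 200
        t = FreqTable(
            chrom=np.full(n, "chr1", dtype=object),
            pos=np.arange(n) * 100_000 + 1,
            freqs={"A": np.ones(n), "B": np.zeros(n),
                   "C": np.ones(n), "D": np.zeros(n)},
        )
        assert f4(t, "A", "B", "C", "D").estimate == 1.0

    def test_matches_brute_force_mean(self, rng):
        t = freq_table(500, rng)
        res = f4(t, "A", "B", "C", "D")
        brute = np.mean(
            [(t.freqs["A"][i] - t.freqs["B"][i]) * (t.freqs["C"][i] - t.freqs["D"][i])
             for i in range(500)]
        )
        assert res.estimate == pytest.approx(brute, abs=1e-15)

    def test_antisymmetry(self, rng):
        t = freq_table(300, rng)
        base = f4(t, "A", "B", "C", "D")
        assert f4(t, "B", "A", "C", "D").estimate == pytest.approx(-base.estimate)
        assert f4(t, "A", "B", "D", "C").estimate == pytest.approx(-base.estimate)

    def test_invariant_to_site_order_within_blocks(self, rng):
        t = freq_table(100, rng)
        perm = np.concatenate([np.arange(50)[::-1], 50 + np.arange(50)[::-1]])
        t2 = FreqTable(
            chrom=t.chrom, pos=t.pos,
            freqs={k: v[perm] for k, v in t.freqs.items()},
        )
        a, b = f4(t, "A", "B", "C", "D"), f4(t2, "A", "B", "C", "D")
        assert a.estimate == pytest.approx(b.estimate, abs=1e-15)
        assert a.jackknife_se == pytest.approx(b.jackknife_se, rel=1e-12)


class TestJackknife:
    def test_se_shrinks_with_block_count(self, rng):
        ses = []
        for n_blocks in (10, 40, 160):
            vals = rng.normal(0, 1, n_blocks * 20)
            ids = np.repeat(np.arange(n_blocks), 20)
            ses.append(block_jackknife(vals, ids)[1])
        # ~ 1/sqrt(blocks): 4x blocks -> ~2x smaller SE
        assert ses[0] > ses[1] > ses[2]
        assert ses[0] / ses[2] == pytest.approx(4.0, rel=0.5)

    def test_positive_when_blocks_differ(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0])
        ids = np.array([0, 0, 1, 1])
        est, se, g = block_jackknife(vals, ids)
        assert est == 1.5 and se > 0 and g == 2


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km((35.0, 135.0), (35.0, 135.0)) == 0.0

    def test_antipodal_half_circumference(self):
        d = haversine_km((0.0, 0.0), (0.0, 180.0))
        assert d == pytest.approx(math.pi * 6371.0, rel=1e-9)

    def test_quarter_circumference(self):
        d = haversine_km((0.0, 0.0), (0.0, 90.0))
        assert d == pytest.approx(math.pi * 6371.0 / 2, rel=1e-9)  # ~10007.54 km

    def test_symmetry(self, rng):
        for _ in range(20):
            p1 = (float(rng.uniform(-90, 90)), float(rng.uniform(-180, 180)))
            p2 = (float(rng.uniform(-90, 90)), float(rng.uniform(-180, 180)))
            assert haversine_km(p1, p2) == pytest.approx(haversine_km(p2, p1))

    def test_custom_radius_scales(self):
        assert haversine_km((0, 0), (0, 90), radius_km=1.0) == pytest.approx(
            math.pi / 2
        )


class TestDriftDistance:
    def make_records(self, f3_values, lons):
        return [
            GeoRecord(f"ind{i}", f, 0.0, lon)
            for i, (f, lon) in enumerate(zip(f3_values, lons))
        ]

    def test_exact_linear_negative(self):
        lons = np.linspace(1, 10, 8)
        dists = [haversine_km((0, 0), (0, l)) for l in lons]
        f3v = [0.25 - 1e-6 * d for d in dists]
        res = drift_distance_test(self.make_records(f3v, lons), (0.0, 0.0))
        assert res["r"] == pytest.approx(-1.0, abs=1e-9)
        assert res["slope"] == pytest.approx(-1e-6, rel=1e-6)
        assert res["p_value"] < 1e-12

    def test_constant_f3_gives_zero_slope_p_one(self):
        res = drift_distance_test(self.make_records([0.2] * 6, range(1, 7)), (0.0, 0.0))
        # exact arithmetic would give slope 0, p 1; allow float rounding
        assert res["slope"] == pytest.approx(0.0, abs=1e-30)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_closed_form_ols(self, rng):
        lons = np.arange(1, 13, dtype=float)
        f3v = rng.normal(0.2, 0.01, 12)
        res = drift_distance_test(self.make_records(f3v, lons), (0.0, 0.0))
        x = np.array([haversine_km((0, 0), (0, l)) for l in lons])
        y = f3v
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        r = np.corrcoef(x, y)[0, 1]
        t = r * math.sqrt(10 / (1 - r * r))
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), 10)
        assert res["slope"] == pytest.approx(slope, rel=1e-12)
        assert res["r"] == pytest.approx(r, rel=1e-12)
        assert res["p_value"] == pytest.approx(p, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="three"):
            drift_distance_test(self.make_records([0.1, 0.2], [1, 2]), (0, 0))
        same = [GeoRecord(f"i{k}", 0.1 * k, 10.0, 20.0) for k in range(4)]
        with pytest.raises(ValueError, match="equidistant"):
            drift_distance_test(same, (0, 0))

    def test_coordinates_validated(self):
        with pytest.raises(ValueError):
            GeoRecord("x", 0.1, 95.0, 0.0)
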