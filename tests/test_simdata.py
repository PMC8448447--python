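"""Generator contracts: determinism, unit conversion, ascertainment and
degradation statistics, and the population-size signal in heterozygosity."""

import warnings

import numpy as np
import pytest
from scipy import stats

from rohabc.simdata import (
    ANCIENT_ID,
    MISSING,
    DemographicScenario,
    GenomeLayout,
    ascertain_sites,
    degrade_calls,
    simulate_scenario,
)

from conftest import make_table

TINY = GenomeLayout(chromosomes=[("chr1", 2_000_000), ("chr2", 2_000_000)])


class TestScenario:
    def test_age_and_split_unit_conversion(self):
        sc = DemographicScenario(T_split=20_000, generation_years=25)
        assert sc.t_split_gen == 800
        assert sc.sample_age_gen == 353  # 8819 / 25 = 352.76, half-up

    def test_rounding_half_up(self):
        sc = DemographicScenario(sample_age=8812.5, T_split=20_000)
        assert sc.sample_age_gen == 353  # 352.5 rounds up

    def test_split_must_predate_sample(self):
        with pytest.raises(ValueError, match="predate"):
            DemographicScenario(T_split=8000, sample_age=8819)

    def test_split_within_scaffold(self):
        with pytest.raises(ValueError, match="scaffold"):
            DemographicScenario(T_split=300_000)

    def test_empty_chromosome_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            GenomeLayout(chromosomes=[])

    def test_panel_floor(self):
        with pytest.raises(ValueError, match="panel_size"):
            simulate_scenario(DemographicScenario(), TINY, 9, 1)


class TestSimulate:
    def test_same_seed_identical_output(self):
        a = simulate_scenario(DemographicScenario(), TINY, 10, 7)
        b = simulate_scenario(DemographicScenario(), TINY, 10, 7)
        assert a == b

    def test_different_seed_differs(self):
        a = simulate_scenario(DemographicScenario(), TINY, 10, 7)
        b = simulate_scenario(DemographicScenario(), TINY, 10, 8)
        assert a != b

    def test_structure_and_invariants(self):
        t = simulate_scenario(DemographicScenario(), TINY, 10, 3)
        assert t.sample_ids[0] == ANCIENT_ID and len(t.sample_ids) == 11
        assert set(t.chromosomes()) == {"chr1", "chr2"}
        for c in t.chromosomes():
            assert (np.diff(t.pos[t.chrom == c]) > 0).all()
        assert set(np.unique(t.gt)).issubset({0, 1, 2})
        assert (t.gq == 99).all() and (t.dp == 30).all()

    def test_ancient_split_ancestor_can_predate_eurasian_split(self):
        # T beyond the EU/EAS divergence must still simulate
        sc = DemographicScenario(T_split=40_000)
        t = simulate_scenario(sc, TINY, 10, 5)
        assert t.n_sites > 0

    def test_heterozygosity_increases_with_population_size(self):
        """Smaller isolated populations lose diversity: mean ancient-sample
        heterozygosity at N=500 is below N=2500 (Wilcoxon p < 0.01)."""
        lay = GenomeLayout(chromosomes=[("chr1", 5_000_000)])
        het = {}
        for N in (500, 2500):
            vals = []
            for rep in range(30):
                t = simulate_scenario(
                    DemographicScenario(N_iso=N), lay, 10, 1000 + rep,
                    recomb_cutoff_gen=2000.0, marker_fraction=0.3,
                )
                a = ascertain_sites(t, lay, rep)
                vals.append(float((a.gt[:, 0] == 1).mean()))
            het[N] = vals
        res = stats.mannwhitneyu(het[500], het[2500], alternative="less")
        assert res.pvalue < 0.01


class TestAscertain:
    def test_monomorphic_panel_gives_empty_output_with_warning(self):
        t = make_table([100, 200, 300], [1, 1, 1])  # single "panel" sample
        t.sample_ids[0] = "panel0"
        t.gt[:] = 0
        with pytest.warns(UserWarning, match="empty"):
            out = ascertain_sites(t, TINY, 1)
        assert out.n_sites == 0

    def test_zero_threshold_infinite_density_is_identity(self):
        t = simulate_scenario(DemographicScenario(), TINY, 10, 11)
        lay = GenomeLayout(
            chromosomes=TINY.chromosomes,
            target_snp_density=np.inf,
            maf_threshold=0.0,
        )
        assert ascertain_sites(t, lay, 1) == t

    def test_thinned_count_is_binomial(self):
        """Thinning to density 1/4060 bp on a 10-Mb chromosome keeps a
        Binomial(n, target/n) number of sites (within 3 SD)."""
        n = 50_000
        pos = np.sort(np.random.default_rng(0).choice(10_000_000, n, replace=False)) + 1
        t = make_table(pos, np.ones(n))  # het everywhere: panel MAF 0.5
        t.sample_ids[0] = "panel0"
        lay = GenomeLayout(
            chromosomes=[("chr1", 10_000_000)],
            target_snp_density=1 / 4060,
            maf_threshold=0.01,
        )
        target = 10_000_000 / 4060
        p = target / n
        sd = np.sqrt(n * p * (1 - p))
        counts = [ascertain_sites(t, lay, seed).n_sites for seed in range(5)]
        for c in counts:
            assert abs(c - target) < 3 * sd

    def test_maf_filter_drops_private_variation(self):
        # ancient-only hets vanish; panel-shared variation survives
        t = simulate_scenario(DemographicScenario(), TINY, 10, 21)
        out = ascertain_sites(t, TINY, 1)
        panel = out.gt[:, 1:]
        poly = (panel.sum(axis=1) > 0) & (panel.sum(axis=1) < 2 * panel.shape[1])
        assert poly.all()


class TestDegrade:
    def test_zero_rates_identity(self):
        t = simulate_scenario(DemographicScenario(), TINY, 10, 2)
        out, counts = degrade_calls(t, 0.0, 0.0, 1)
        assert out == t
        assert counts == {"set_missing": 0, "het_flipped": 0}

    def test_all_missing(self):
        t = simulate_scenario(DemographicScenario(), TINY, 10, 2)
        out, counts = degrade_calls(t, 1.0, 0.0, 1)
        assert (out.gt == MISSING).all()
        assert counts["set_missing"] == t.gt.size

    def test_missing_count_is_binomial(self):
        n = 10_000
        t = make_table(np.arange(n) * 10 + 1, np.zeros(n))
        out, counts = degrade_calls(t, 0.1, 0.0, 99)
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(counts["set_missing"] - 1000) < 3 * sd

    def test_het_flips_go_to_homozygotes(self):
        n = 5000
        t = make_table(np.arange(n) * 10 + 1, np.ones(n))
        out, counts = degrade_calls(t, 0.0, 1.0, 5)
        assert counts["het_flipped"] == n
        assert set(np.unique(out.gt)) <= {0, 2}

    def test_rates_validated(self):
        t = make_table([1], [0])
        with pytest.raises(ValueError):
            degrade_calls(t, -0.1, 0, 1)
        with pytest.raises(ValueError):
            degrade_calls(t, 0, 1.5, 1)
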