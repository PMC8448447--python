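"""Coalescent simulation of an ancient diploid genome from an isolated lineage.

The generator emulates the study system: a single ancient individual sampled
``sample_age`` years before present from a lineage of constant effective size
``N_iso`` that split ``T_split`` years ago from the East Asian branch of a
three-population Out-of-Africa (OOA) demographic scaffold, together with a
modern East Asian diploid panel used for allele-frequency ascertainment.
Each autosome is an independent coalescent replicate.

Ascertainment mimics array-like marker selection: sites are filtered to a
minor-allele-frequency floor in the modern panel and thinned uniformly at
random to a genome-wide marker density (the density, not the mutational
class, is what matters for downstream run-of-homozygosity calling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import msprime
import numpy as np

__all__ = [
    "OOAScaffold",
    "DemographicScenario",
    "GenomeLayout",
    "GenotypeTable",
    "hg19_autosomes",
    "build_demography",
    "simulate_scenario",
    "ascertain_sites",
    "degrade_calls",
]

# Total SNPs on the emulated transversion/MAF-ascertained panel, genome-wide.
TARGET_TOTAL_SNPS = 660_027

MISSING = -1  # missing genotype dosage sentinel

# hg19 autosome lengths (bp), chr1..chr22.
_HG19_AUTOSOME_BP = [
    249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
    159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
    115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
    59128983, 63025520, 48129895, 51304566,
]


def hg19_autosomes() -> list[tuple[str, int]]:
    """(name, length_bp) pairs for the 22 human autosomes (hg19)."""
    return [(f"chr{i + 1}", L) for i, L in enumerate(_HG19_AUTOSOME_BP)]


@dataclass(frozen=True)
class OOAScaffold:
    """Three-population Out-of-Africa scaffold, in the classic
    maximum-likelihood parameterization (sizes in diploids, times in
    generations, growth and migration per generation)."""

    n_ancestral: float = 7300.0
    n_african: float = 12300.0
    n_bottleneck: float = 2100.0
    n_european_0: float = 1000.0   # size at the EU/EAS split, grows to present
    n_east_asian_0: float = 510.0  # size at the EU/EAS split, grows to present
    growth_european: float = 0.004
    growth_east_asian: float = 0.0055
    t_african_expansion_gen: float = 8800.0
    t_out_of_africa_gen: float = 5600.0
    t_eu_eas_split_gen: float = 848.0
    m_african_bottleneck: float = 25e-5
    m_african_european: float = 3e-5
    m_african_east_asian: float = 1.9e-5
    m_european_east_asian: float = 9.6e-5


@dataclass(frozen=True)
class DemographicScenario:
    """An isolated lineage of constant size ``N_iso`` splitting ``T_split``
    years ago from the East Asian branch of the OOA scaffold, with one
    diploid sampled ``sample_age`` years before present.

    ``sample_age`` defaults to 8819 years BP, the median calibrated date of
    the oldest ancient individual the pipeline is designed around.
    """

    N_iso: float = 1000.0
    T_split: float = 20_000.0          # years before present
    sample_age: float = 8819.0         # years before present
    generation_years: float = 25.0
    ooa_params: OOAScaffold = field(default_factory=OOAScaffold)
    mutation_rate: float = 2.35e-8     # per bp per generation
    recombination_rate: float = 1.0e-8  # per bp per generation

    def __post_init__(self) -> None:
        if self.N_iso <= 0:
            raise ValueError("N_iso must be positive")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be positive")
        if self.T_split <= self.sample_age:
            raise ValueError(
                f"T_split ({self.T_split} yBP) must predate sample_age "
                f"({self.sample_age} yBP): the lineage must exist when sampled"
            )
        if self.t_split_gen >= self.ooa_params.t_african_expansion_gen:
            raise ValueError("T_split lies beyond the OOA scaffold's root epoch")

    @property
    def sample_age_gen(self) -> int:
        """Sample age in generations, rounded half-up."""
        return _round_half_up(self.sample_age / self.generation_years)

    @property
    def t_split_gen(self) -> int:
        """Split time in generations, rounded half-up."""
        return _round_half_up(self.T_split / self.generation_years)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome structure and marker ascertainment targets."""

    chromosomes: tuple[tuple[str, int], ...] = None  # type: ignore[assignment]
    target_snp_density: float = None  # type: ignore[assignment]  # sites per bp
    maf_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.chromosomes is None:
            object.__setattr__(self, "chromosomes", tuple(hg19_autosomes()))
        else:
            object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if len(self.chromosomes) == 0:
            raise ValueError("chromosome list must be non-empty")
        if any(L <= 0 for _, L in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.target_snp_density is None:
            # genome-wide marker density of the emulated ascertainment panel,
            # fixed so miniature layouts keep realistic marker spacing
            object.__setattr__(
                self, "target_snp_density", TARGET_TOTAL_SNPS / sum(_HG19_AUTOSOME_BP)
            )
        if self.target_snp_density <= 0:
            raise ValueError("target_snp_density must be positive")
        if not (0.0 <= self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must lie in [0, 0.5)")

    @property
    def total_bp(self) -> int:
        return sum(L for _, L in self.chromosomes)

    def subset(self, names) -> "GenomeLayout":
        """Layout restricted to the named chromosomes (density unchanged)."""
        wanted = [c for c in self.chromosomes if c[0] in set(names)]
        if not wanted:
            raise ValueError("chromosome subset is empty")
        return replace(
            self,
            chromosomes=tuple(wanted),
            target_snp_density=self.target_snp_density,
        )


@dataclass
class GenotypeTable:
    """Per-site diploid alt-allele dosages with quality annotations.

    ``gt`` is (n_sites, n_samples) with entries in {0, 1, 2} or -1 (missing);
    ``gq``/``dp`` share that shape. Positions are 1-based and strictly
    increasing within a chromosome.
    """

    chrom: np.ndarray       # (n_sites,) str
    pos: np.ndarray         # (n_sites,) int64, 1-based
    gt: np.ndarray          # (n_sites, n_samples) int8
    gq: np.ndarray          # (n_sites, n_samples) int32
    dp: np.ndarray          # (n_sites, n_samples) int32
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "gt", "gq", "dp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match pos")
        if self.gt.ndim != 2 or self.gt.shape[1] != len(self.sample_ids):
            raise ValueError("gt shape inconsistent with sample_ids")
        self._check_sorted()
        bad = ~np.isin(self.gt, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype dosages must be in {0,1,2,missing}")

    def _check_sorted(self) -> None:
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def take(self, mask_or_idx) -> "GenotypeTable":
        return GenotypeTable(
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            gt=self.gt[mask_or_idx],
            gq=self.gq[mask_or_idx],
            dp=self.dp[mask_or_idx],
            sample_ids=list(self.sample_ids),
        )

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.gq, other.gq)
            and np.array_equal(self.dp, other.dp)
        )


ANCIENT_ID = "ancient0"

# Synthetic calls carry passing constants unless explicitly degraded.
DEFAULT_GQ = 99
DEFAULT_DP = 30


def build_demography(scenario: DemographicScenario) -> msprime.Demography:
    """msprime demography: OOA scaffold plus the isolated branch.

    The isolated population splits from the East Asian branch when
    ``T_split`` postdates the EU/EAS divergence, and from the ancestral
    Eurasian bottleneck population when it predates it (the parameter grid
    extends past the EU/EAS split).
    """
    p = scenario.ooa_params
    t_split = scenario.t_split_gen
    d = msprime.Demography()
    d.add_population(name="AFR", initial_size=p.n_african, initially_active=True)
    d.add_population(
        name="EUR",
        initial_size=p.n_european_0 * math.exp(p.growth_european * p.t_eu_eas_split_gen),
        growth_rate=p.growth_european,
    )
    d.add_population(
        name="EAS",
        initial_size=p.n_east_asian_0
        * math.exp(p.growth_east_asian * p.t_eu_eas_split_gen),
        growth_rate=p.growth_east_asian,
        initially_active=True,
    )
    d.add_population(name="ISO", initial_size=scenario.N_iso)
    d.add_population(name="B", initial_size=p.n_bottleneck, initially_active=True)

    d.set_symmetric_migration_rate(["AFR", "EUR"], p.m_african_european)
    d.set_symmetric_migration_rate(["AFR", "EAS"], p.m_african_east_asian)
    d.set_symmetric_migration_rate(["EUR", "EAS"], p.m_european_east_asian)

    iso_parent = "EAS" if t_split < p.t_eu_eas_split_gen else "B"
    d.add_population_split(time=t_split, derived=["ISO"], ancestral=iso_parent)
    d.add_population_split(
        time=p.t_eu_eas_split_gen, derived=["EUR", "EAS"], ancestral="B"
    )
    d.add_symmetric_migration_rate_change(
        time=p.t_eu_eas_split_gen, populations=["AFR", "B"],
        rate=p.m_african_bottleneck,
    )
    d.add_population_split(
        time=p.t_out_of_africa_gen, derived=["B"], ancestral="AFR"
    )
    d.add_population_parameters_change(
        time=p.t_african_expansion_gen, population="AFR",
        initial_size=p.n_ancestral, growth_rate=0,
    )
    d.sort_events()
    return d


def _chrom_seeds(seed: int, n: int) -> np.ndarray:
    """Independent msprime seed pairs per chromosome, derived reproducibly."""
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2 * n, dtype=np.uint64)
    return (state % np.uint64(2**31 - 1) + np.uint64(1)).reshape(n, 2)


def simulate_scenario(
    scenario: DemographicScenario,
    layout: GenomeLayout,
    panel_size: int,
    seed: int,
    *,
    recomb_cutoff_gen: float | None = None,
    marker_fraction: float = 1.0,
) -> GenotypeTable:
    """Simulate one ancient diploid plus a modern East Asian panel.

    Each chromosome is an independent coalescent replicate; the returned
    table holds the full variant set (before ascertainment), the ancient
    sample first.

    Two performance options preserve single-site statistics exactly:

    * ``recomb_cutoff_gen`` — simulate recombination exactly up to this
      time, then continue the remaining lineages to coalescence with
      recombination switched off. Marginal (per-site) genealogies remain
      draws from the model; only the spatial correlation of deep TMRCA is
      approximated. Run-of-homozygosity structure lives in the recent
      epochs, so a cutoff well past the split time is safe.
    * ``marker_fraction`` — emit this Bernoulli fraction of mutations by
      scaling the mutation rate (exact Poisson thinning of the mutation
      process), matching a uniform post-hoc thinning in distribution.
    """
    if panel_size < 10:
        raise ValueError("panel_size must be >= 10 for MAF ascertainment")
    if not (0.0 < marker_fraction <= 1.0):
        raise ValueError("marker_fraction must lie in (0, 1]")
    demography = build_demography(scenario)
    samples = [
        msprime.SampleSet(1, population="ISO", time=scenario.sample_age_gen, ploidy=2),
        msprime.SampleSet(panel_size, population="EAS", time=0, ploidy=2),
    ]
    if recomb_cutoff_gen is not None and recomb_cutoff_gen <= scenario.t_split_gen:
        # keep exact recombination through the isolation epoch
        recomb_cutoff_gen = scenario.t_split_gen + 100.0

    seeds = _chrom_seeds(seed, len(layout.chromosomes))
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    gts: list[np.ndarray] = []
    for (name, length), (s_anc, s_mut) in zip(layout.chromosomes, seeds):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=length,
            recombination_rate=scenario.recombination_rate,
            random_seed=int(s_anc),
            end_time=recomb_cutoff_gen,
        )
        if recomb_cutoff_gen is not None:
            ts = msprime.sim_ancestry(
                initial_state=ts,
                demography=demography,
                recombination_rate=0,
                random_seed=int(s_anc),
            )
        mts = msprime.sim_mutations(
            ts,
            rate=scenario.mutation_rate * marker_fraction,
            random_seed=int(s_mut),
            model=msprime.BinaryMutationModel(),
        )
        g = mts.genotype_matrix()           # (sites, haplotypes)
        n_dip = g.shape[1] // 2
        dosage = (g[:, 0::2] + g[:, 1::2]).astype(np.int8)
        # tskit sites sit on a 0-based continuum; report 1-based integers
        pos = np.floor(mts.sites_position).astype(np.int64) + 1
        keep = np.concatenate(([True], np.diff(pos) > 0))  # drop rare collisions
        chroms.append(np.full(int(keep.sum()), name, dtype=object))
        poss.append(pos[keep])
        gts.append(dosage[keep][:, :n_dip])

    gt = np.concatenate(gts) if gts else np.empty((0, panel_size + 1), dtype=np.int8)
    n_sites = sum(len(p) for p in poss)
    sample_ids = [ANCIENT_ID] + [f"panel{i}" for i in range(panel_size)]
    return GenotypeTable(
        chrom=np.concatenate(chroms) if chroms else np.empty(0, dtype=object),
        pos=np.concatenate(poss) if poss else np.empty(0, dtype=np.int64),
        gt=gt,
        gq=np.full((n_sites, panel_size + 1), DEFAULT_GQ, dtype=np.int32),
        dp=np.full((n_sites, panel_size + 1), DEFAULT_DP, dtype=np.int32),
        sample_ids=sample_ids,
    )


def panel_maf(table: GenotypeTable) -> np.ndarray:
    """Minor-allele frequency per site over the panel samples (all but the
    ancient sample), treating missing dosages as unobserved."""
    panel = np.array([s != ANCIENT_ID for s in table.sample_ids])
    g = table.gt[:, panel].astype(np.float64)
    obs = g != MISSING
    alt = np.where(obs, g, 0.0).sum(axis=1)
    n = 2.0 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    return np.minimum(f, 1.0 - f)


def ascertain_sites(
    table: GenotypeTable, layout: GenomeLayout, seed: int
) -> GenotypeTable:
    """Panel-MAF filter followed by uniform thinning to the target density.

    Sites with panel minor-allele frequency below ``layout.maf_threshold``
    are dropped; survivors are kept independently with probability
    ``target_count / n_survivors`` so the expected marker count matches
    ``target_snp_density`` over the layout. Ordering is preserved.
    """
    maf = panel_maf(table)
    keep = maf >= layout.maf_threshold
    kept = table.take(keep)
    n = kept.n_sites
    target = layout.target_snp_density * layout.total_bp
    if n > 0 and np.isfinite(target) and target < n:
        rng = np.random.default_rng(seed)
        kept = kept.take(rng.random(n) < target / n)
    if kept.n_sites == 0:
        warnings.warn("ascertainment produced an empty site list", stacklevel=2)
    return kept


def degrade_calls(
    table: GenotypeTable,
    missing_rate: float,
    het_error_rate: float,
    seed: int,
) -> tuple[GenotypeTable, dict[str, int]]:
    """Robustness fixture: randomly missing calls and het→hom flips.

    Each genotype is independently set missing with ``missing_rate``; each
    surviving heterozygote is flipped to a random homozygote with
    ``het_error_rate``. Returns the degraded table and alteration counts.
    """
    for r in (missing_rate, het_error_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gt = table.gt.copy()
    to_missing = rng.random(gt.shape) < missing_rate
    n_missing = int((to_missing & (gt != MISSING)).sum())
    gt[to_missing] = MISSING
    het = gt == 1
    flip = het & (rng.random(gt.shape) < het_error_rate)
    gt[flip] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(flip.sum()))
    out = GenotypeTable(
        chrom=table.chrom, pos=table.pos, gt=gt,
        gq=table.gq, dp=table.dp, sample_ids=list(table.sample_ids),
    )
    return out, {"set_missing": n_missing, "het_flipped": int(flip.sum())}
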