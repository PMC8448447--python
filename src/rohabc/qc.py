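"""Ancient-sample QC and date utilities.

Molecular sexing from the Y-chromosome read ratio Ry (female below 0.016,
male above 0.075, unassigned between); mitochondrial contamination as the
pooled rate of secondary bases mismatching the consensus at
haplotype-defining and private sites, with a damage-aware variant that
drops C/G sites; and conversion of admixture dates in generations to
calendar years before present anchored on a reference sample age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SexAssignment",
    "PileupSite",
    "ContaminationEstimate",
    "AdmixtureDate",
    "assign_sex",
    "mt_contamination",
    "reference_age",
    "convert_admixture_date",
    "RY_FEMALE_MAX",
    "RY_MALE_MIN",
]

RY_FEMALE_MAX = 0.016  # call female strictly below
RY_MALE_MIN = 0.075    # call male strictly above

_DAMAGE_BASES = frozenset("CG")  # deamination-prone


@dataclass(frozen=True)
class SexAssignment:
    n_y_reads: int
    n_sex_reads: int
    ry: float
    call: str  # "female" | "male" | "unassigned"


@dataclass(frozen=True)
class PileupSite:
    """Base counts at one diagnostic mtDNA position."""

    position: int
    consensus: str
    counts: dict[str, int]  # A/C/G/T -> count

    def __post_init__(self) -> None:
        if self.consensus not in "ACGT":
            raise ValueError("consensus must be one of A/C/G/T")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("base counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def mismatches(self) -> int:
        return sum(v for b, v in self.counts.items() if b != self.consensus)

    @property
    def damage_prone(self) -> bool:
        """True if the consensus or any observed mismatch base is C or G."""
        if self.consensus in _DAMAGE_BASES:
            return True
        return any(
            v > 0 and b in _DAMAGE_BASES
            for b, v in self.counts.items()
            if b != self.consensus
        )


@dataclass(frozen=True)
class ContaminationEstimate:
    rate_all: float
    rate_no_cg: float
    n_sites: int
    n_sites_no_cg: int


@dataclass(frozen=True)
class AdmixtureDate:
    generations: float
    se_generations: float
    generation_years: float
    reference_age_bp: float
    years_bp: float
    se_years: float


def assign_sex(n_y_reads: int, n_sex_reads: int) -> SexAssignment:
    """Ry sexing: Ry = Y reads / (X + Y) reads; female if Ry < 0.016,
    male if Ry > 0.075, otherwise unassigned."""
    if n_sex_reads <= 0:
        raise ValueError("n_sex_reads must be positive")
    if not (0 <= n_y_reads <= n_sex_reads):
        raise ValueError("n_y_reads must lie in [0, n_sex_reads]")
    ry = n_y_reads / n_sex_reads
    if ry < RY_FEMALE_MAX:
        call = "female"
    elif ry > RY_MALE_MIN:
        call = "male"
    else:
        call = "unassigned"
    return SexAssignment(n_y_reads, n_sex_reads, ry, call)


def mt_contamination(sites: list[PileupSite]) -> ContaminationEstimate:
    """Pooled mismatch rate over diagnostic sites, with and without
    damage-prone (C/G) sites.

    ``rate_all`` pools mismatching bases over all supplied sites;
    ``rate_no_cg`` repeats the computation after dropping any site whose
    consensus or observed mismatch base is C or G (possible postmortem
    deamination rather than contamination).
    """
    if not sites:
        raise ValueError("site list must be non-empty")
    total = sum(s.total for s in sites)
    if total <= 0:
        raise ValueError("no coverage at supplied sites")
    rate_all = sum(s.mismatches for s in sites) / total
    kept = [s for s in sites if not s.damage_prone]
    denom = sum(s.total for s in kept)
    rate_no_cg = (sum(s.mismatches for s in kept) / denom) if denom else 0.0
    return ContaminationEstimate(
        rate_all=rate_all, rate_no_cg=rate_no_cg,
        n_sites=len(sites), n_sites_no_cg=len(kept),
    )


def reference_age(median_dates_bp: list[float]) -> int:
    """Mean of median calibrated dates, rounded half-up to integer years."""
    if not median_dates_bp:
        raise ValueError("need at least one date")
    return int(math.floor(sum(median_dates_bp) / len(median_dates_bp) + 0.5))


def convert_admixture_date(
    generations: float,
    se_generations: float = 0.0,
    generation_years: float = 25.0,
    reference_age_bp: float = 0.0,
) -> AdmixtureDate:
    """Convert an admixture date in generations before a reference sample to
    calendar years before present: ref_age + generations x generation_years."""
    if generations < 0 or se_generations < 0 or generation_years <= 0:
        raise ValueError("dates and errors must be non-negative, generation_years positive")
    return AdmixtureDate(
        generations=generations,
        se_generations=se_generations,
        generation_years=generation_years,
        reference_age_bp=reference_age_bp,
        years_bp=reference_age_bp + generations * generation_years,
        se_years=se_generations * generation_years,
    )
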