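"""Rejection-ABC likelihood surface over an (N, T) grid, and approximate
Bayes factors.

For every combination of isolated-lineage size N and split time T, the
forward pipeline (coalescent simulation -> marker ascertainment -> ROH
calling -> length spectrum) is replicated; the distance of each simulated
spectrum from the observed one is recorded. A single tolerance epsilon is
the ``acceptance_quantile`` of the distances pooled across the whole grid,
and the approximate likelihood of a grid point is the fraction of its own
replicates accepted at that tolerance. Model comparison uses
log10 approximate Bayes factors against the maximum-likelihood point;
log10 aBF > 2 is read as decisive evidence against the weaker model, and a
point with zero likelihood has an unmeasurable (NA) aBF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .roh import DEFAULT_BIN_EDGES_MB, ROHParams, ROHSpectrum, call_roh, compute_spectrum
from .simdata import (
    ANCIENT_ID,
    DemographicScenario,
    GenomeLayout,
    ascertain_sites,
    simulate_scenario,
)

__all__ = [
    "GridSpec",
    "GridPoint",
    "spectrum_distance",
    "simulate_spectrum",
    "fit_grid",
    "compute_abf",
    "is_decisive",
    "DECISIVE_LOG10_ABF",
]

DECISIVE_LOG10_ABF = 2.0

# Broad-search stage omits the two largest autosomes; the final stage uses all.
COARSE_CHROMS = tuple(f"chr{i}" for i in range(3, 23))
FULL_CHROMS = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class GridSpec:
    """The (N, T) search grid and ABC settings.

    ``N_values`` are diploid effective sizes; ``T_values`` are split times
    in years before present. ``chromosome_subset`` selects which layout
    chromosomes enter a stage (the broad search drops chr1-2; the final
    evaluation uses everything). Simulation performance options are carried
    here so grid fits and the observed genome can share them.
    """

    N_values: tuple[float, ...] = (500, 1000, 1500, 2000, 2500)
    T_values: tuple[float, ...] = (10_000, 15_000, 20_000, 25_000, 30_000, 35_000, 40_000)
    replicates_per_point: int = 50
    acceptance_quantile: float = 0.05
    chromosome_subset: tuple[str, ...] | None = None
    seed: int = 1
    panel_size: int = 10
    scale_bins: bool = False
    recomb_cutoff_gen: float | None = 2000.0
    marker_fraction: float = 0.2  # exact Poisson thinning; headroom measured

    def __post_init__(self) -> None:
        if not self.N_values or not self.T_values:
            raise ValueError("grid must be non-empty")
        if self.replicates_per_point < 1:
            raise ValueError("replicates_per_point must be >= 1")
        if not (0.0 < self.acceptance_quantile < 1.0):
            raise ValueError("acceptance_quantile must lie in (0, 1)")
        object.__setattr__(self, "N_values", tuple(self.N_values))
        object.__setattr__(self, "T_values", tuple(self.T_values))
        if self.chromosome_subset is not None:
            object.__setattr__(
                self, "chromosome_subset", tuple(self.chromosome_subset)
            )


@dataclass
class GridPoint:
    """One (N, T) model with its ABC summary."""

    N: float
    T: float
    distances: np.ndarray = field(repr=False)
    n_accepted: int = 0
    likelihood: float = 0.0
    log10_aBF: float = math.nan
    is_map: bool = False

    @property
    def aBF_is_na(self) -> bool:
        return math.isnan(self.log10_aBF)


def spectrum_distance(
    observed: ROHSpectrum, simulated: ROHSpectrum, *, scale: np.ndarray | None = None
) -> float:
    """Euclidean norm of per-bin total-Mb differences.

    ``scale`` optionally divides each bin difference (a per-bin-scaled
    variant); edges must match exactly.
    """
    if observed.bin_edges_mb != simulated.bin_edges_mb:
        raise ValueError("spectra use different bin edges")
    diff = observed.totals - simulated.totals
    if scale is not None:
        diff = diff / np.asarray(scale, dtype=float)
    return float(np.sqrt(np.sum(diff * diff)))


def _sub_seed(seed: int, N: float, T: float, rep: int) -> int:
    """Deterministic per-replicate seed from (master seed, N, T, index)."""
    ss = np.random.SeedSequence([int(seed), int(N), int(T), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def simulate_spectrum(
    scenario: DemographicScenario,
    layout: GenomeLayout,
    roh_params: ROHParams,
    seed: int,
    *,
    panel_size: int = 10,
    bin_edges_mb=DEFAULT_BIN_EDGES_MB,
    recomb_cutoff_gen: float | None = 2000.0,
    marker_fraction: float = 1.0,
) -> ROHSpectrum:
    """One forward replicate: simulate, ascertain, call ROH, bin."""
    table = simulate_scenario(
        scenario, layout, panel_size, seed,
        recomb_cutoff_gen=recomb_cutoff_gen, marker_fraction=marker_fraction,
    )
    asc = ascertain_sites(table, layout, seed)
    segments = call_roh(asc, ANCIENT_ID, roh_params)
    return compute_spectrum(segments, layout.total_bp, bin_edges_mb)


def fit_grid(
    observed: ROHSpectrum,
    scenario_template: DemographicScenario,
    layout: GenomeLayout,
    grid: GridSpec,
    roh_params: ROHParams | None = None,
) -> list[GridPoint]:
    """Rejection-ABC over the (N, T) grid against an observed ROH spectrum.

    The tolerance is the pooled ``acceptance_quantile`` of all replicate
    distances across the grid; each point's likelihood is the fraction of
    its replicates within tolerance. Raises if nothing is accepted anywhere
    (no model fits at this tolerance). aBFs are filled in via
    :func:`compute_abf`.
    """
    roh_params = roh_params or ROHParams()
    if grid.chromosome_subset is not None:
        layout = layout.subset(grid.chromosome_subset)
    bins = observed.bin_edges_mb
    scale = None
    if grid.scale_bins:
        scale = np.maximum(observed.totals, 1.0)

    points: list[GridPoint] = []
    for N, T in product(grid.N_values, grid.T_values):
        scenario = replace(scenario_template, N_iso=float(N), T_split=float(T))
        dists = np.empty(grid.replicates_per_point)
        for rep in range(grid.replicates_per_point):
            sim = simulate_spectrum(
                scenario, layout, roh_params,
                _sub_seed(grid.seed, N, T, rep),
                panel_size=grid.panel_size,
                bin_edges_mb=bins,
                recomb_cutoff_gen=grid.recomb_cutoff_gen,
                marker_fraction=grid.marker_fraction,
            )
            dists[rep] = spectrum_distance(observed, sim, scale=scale)
        points.append(GridPoint(N=float(N), T=float(T), distances=dists))

    pooled = np.concatenate([p.distances for p in points])
    epsilon = float(np.quantile(pooled, grid.acceptance_quantile))
    for p in points:
        p.n_accepted = int((p.distances <= epsilon).sum())
        p.likelihood = p.n_accepted / grid.replicates_per_point
    if all(p.n_accepted == 0 for p in points):
        raise RuntimeError("no model fits at this tolerance")
    return compute_abf(points)


def compute_abf(points: list[GridPoint]) -> list[GridPoint]:
    """log10 approximate Bayes factors against the maximum-likelihood point.

    Exactly one point is flagged ``is_map``; ties at the maximum are broken
    deterministically (smallest N, then smallest T) and logged. Points with
    zero likelihood get NA (NaN): the aBF is not measurable there. The
    designated point gets exactly 0; a tied runner-up also evaluates to 0,
    which is the mathematically honest value.
    """
    if not points:
        raise ValueError("empty grid")
    best = max(points, key=lambda p: (p.likelihood, -p.N, -p.T))
    ties = [p for p in points if p is not best and p.likelihood == best.likelihood]
    if ties:
        logging.getLogger("rohabc").info(
            "MAP tie at L=%.4g broken to (N=%g, T=%g); tied: %s",
            best.likelihood, best.N, best.T,
            [(p.N, p.T) for p in ties],
        )
    for p in points:
        p.is_map = p is best
        if p.likelihood == 0.0:
            p.log10_aBF = math.nan
        elif p is best:
            p.log10_aBF = 0.0
        else:
            p.log10_aBF = math.log10(best.likelihood / p.likelihood)
    return points


def is_decisive(log10_aBF: float) -> bool:
    """Decisive evidence against a model: log10 aBF strictly above 2, or NA
    (zero likelihood: infinitely disfavored)."""
    return math.isnan(log10_aBF) or log10_aBF > DECISIVE_LOG10_ABF
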