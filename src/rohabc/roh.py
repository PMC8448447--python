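"""Sliding-window run-of-homozygosity (ROH) calling and length spectra.

The caller reproduces the classic PLINK ``--homozyg`` parameterization used
for ancient diploid genomes: 50-SNP windows tolerate at most one
heterozygote and five missing calls; a site belongs to a run when at least
5% of the windows covering it are homozygous-accepting; candidate runs are
split at inter-marker gaps above 100 kb and kept when they carry >= 50 SNPs,
span >= 500 kb, and average at most 50 kb per SNP.

Spectra bin each segment's full length (Mb) into half-open length classes
between 0.5 and 100 Mb; the top bin is closed. Short ROH reflect ancient
small population size, long ROH recent inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import MISSING, GenotypeTable

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHSpectrum",
    "DEFAULT_BIN_EDGES_MB",
    "call_roh",
    "compute_spectrum",
]

DEFAULT_BIN_EDGES_MB = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 100.0)


@dataclass(frozen=True)
class ROHParams:
    """PLINK-style ``--homozyg`` flags. Defaults are the printed flag set;
    ``window_missing`` is the tool's documented default (the run listed only
    non-default flags)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 500.0
    max_gap_kb: float = 100.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snp <= 0 or self.min_snp <= 0:
            raise ValueError("SNP counts must be positive")
        if self.window_het < 0 or self.window_missing < 0:
            raise ValueError("window tolerances must be non-negative")
        if self.min_kb <= 0 or self.max_gap_kb <= 0 or self.min_density_kb_per_snp <= 0:
            raise ValueError("kb parameters must be positive")
        if not (0.0 < self.window_threshold <= 1.0):
            raise ValueError("window_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One called homozygous segment, 1-based inclusive coordinates."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_snp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start must not exceed end")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0

    @property
    def length_mb(self) -> float:
        return self.length_kb / 1000.0


@dataclass(frozen=True)
class ROHSpectrum:
    """Total ROH length (Mb) per segment-length bin, plus the fraction of
    the assayed genome in ROH."""

    bin_edges_mb: tuple[float, ...]
    total_mb_per_bin: tuple[float, ...]
    genome_fraction: float

    def __post_init__(self) -> None:
        if len(self.total_mb_per_bin) != len(self.bin_edges_mb) - 1:
            raise ValueError("need one bin total per pair of adjacent edges")

    @property
    def totals(self) -> np.ndarray:
        return np.asarray(self.total_mb_per_bin, dtype=float)


def _eligible_sites(g: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per-site eligibility under the sliding-window rule."""
    n = len(g)
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    # sliding sums over all n-w+1 windows
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(mis)))
    win_het = chet[w:] - chet[:-w]
    win_mis = cmis[w:] - cmis[:-w]
    accept = (win_het <= params.window_het) & (win_mis <= params.window_missing)
    # windows covering site j start in [max(0, j-w+1), min(j, n-w)]
    cacc = np.concatenate(([0], np.cumsum(accept.astype(np.int64))))
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_cover = hi - lo + 1
    n_hit = cacc[hi + 1] - cacc[lo]
    return n_hit / n_cover >= params.window_threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(mask) - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def call_roh(
    table: GenotypeTable, sample: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call ROH segments for one sample, each chromosome independently.

    Chromosomes with fewer sites than one window yield no segments.
    Returned segments are sorted and non-overlapping.
    """
    params = params or ROHParams()
    col = table.sample_index(sample)
    segments: list[ROHSegment] = []
    max_gap_bp = params.max_gap_kb * 1000.0
    for name in table.chromosomes():
        sel = table.chrom == name
        pos = table.pos[sel]
        g = table.gt[sel, col]
        eligible = _eligible_sites(g, params)
        for s, e in _runs(eligible):
            # split candidate runs at large inter-marker gaps
            cut_points = [s]
            gaps = np.flatnonzero(np.diff(pos[s : e + 1]) > max_gap_bp)
            for gidx in gaps:
                cut_points.append(s + gidx + 1)
            bounds = cut_points + [e + 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                b -= 1
                n_snp = b - a + 1
                length_kb = (pos[b] - pos[a] + 1) / 1000.0
                if (
                    n_snp >= params.min_snp
                    and length_kb >= params.min_kb
                    and length_kb / n_snp <= params.min_density_kb_per_snp
                ):
                    segments.append(
                        ROHSegment(name, int(pos[a]), int(pos[b]), int(n_snp))
                    )
    return segments


def compute_spectrum(
    segments: list[ROHSegment],
    assayed_length_bp: float,
    bin_edges_mb=DEFAULT_BIN_EDGES_MB,
) -> ROHSpectrum:
    """Bin segment lengths into the 0.5-100 Mb spectrum.

    Each in-range segment contributes its full length (Mb) to the half-open
    bin [e_i, e_{i+1}) containing it; the top bin is closed at 100 Mb.
    ``genome_fraction`` is total ROH bp (all in-range segments) over the
    assayed genome length.
    """
    if assayed_length_bp <= 0:
        raise ValueError("assayed_length_bp must be positive")
    edges = np.asarray(bin_edges_mb, dtype=float)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 0.5 or edges[-1] != 100.0:
        raise ValueError("spectrum spans 0.5 to 100 Mb")
    totals = np.zeros(len(edges) - 1)
    roh_bp = 0
    for seg in segments:
        mb = seg.length_mb
        if not (edges[0] <= mb <= edges[-1]):
            continue
        idx = min(np.searchsorted(edges, mb, side="right") - 1, len(totals) - 1)
        totals[idx] += mb
        roh_bp += seg.end_bp - seg.start_bp + 1
    return ROHSpectrum(
        bin_edges_mb=tuple(edges.tolist()),
        total_mb_per_bin=tuple(totals.tolist()),
        genome_fraction=roh_bp / assayed_length_bp,
    )
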