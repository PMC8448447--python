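"""Shared fixtures: toy genotype tables and the naive ROH reference caller."""

from __future__ import annotations

import numpy as np
import pytest

from rohabc.roh import ROHParams
from rohabc.simdata import MISSING, GenotypeTable


def make_table(
    pos, genotypes, chrom="chr1", sample="s0", gq=99, dp=30
) -> GenotypeTable:
    """Single-sample table from explicit positions and dosages."""
    pos = np.asarray(pos, dtype=np.int64)
    g = np.asarray(genotypes, dtype=np.int8).reshape(-1, 1)
    n = len(pos)
    return GenotypeTable(
        chrom=np.full(n, chrom, dtype=object),
        pos=pos,
        gt=g,
        gq=np.full((n, 1), gq, dtype=np.int32),
        dp=np.full((n, 1), dp, dtype=np.int32),
        sample_ids=[sample],
    )


def brute_force_roh(pos, genotypes, params: ROHParams):
    """Naive window-enumeration reference for the ROH caller.

    Enumerates every window, every covering-window fraction, every candidate
    run and every final filter with plain Python loops. Returns
    (start_bp, end_bp, n_snp) tuples.
    """
    pos = list(pos)
    g = list(genotypes)
    n = len(g)
    w = params.window_snp
    if n < w:
        eligible = [False] * n
    else:
        accepting = []
        for i in range(n - w + 1):
            window = g[i : i + w]
            n_het = sum(1 for x in window if x == 1)
            n_mis = sum(1 for x in window if x == MISSING)
            accepting.append(
                n_het <= params.window_het and n_mis <= params.window_missing
            )
        eligible = []
        for j in range(n):
            covering = [
                accepting[i] for i in range(max(0, j - w + 1), min(j, n - w) + 1)
            ]
            frac = sum(covering) / len(covering)
            eligible.append(frac >= params.window_threshold)

    runs = []
    i = 0
    while i < n:
        if eligible[i]:
            j = i
            while j + 1 < n and eligible[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    candidates = []
    for s, e in runs:
        start = s
        for k in range(s, e):
            if pos[k + 1] - pos[k] > params.max_gap_kb * 1000:
                candidates.append((start, k))
                start = k + 1
        candidates.append((start, e))

    out = []
    for a, b in candidates:
        n_snp = b - a + 1
        length_kb = (pos[b] - pos[a] + 1) / 1000.0
        if (
            n_snp >= params.min_snp
            and length_kb >= params.min_kb
            and length_kb / n_snp <= params.min_density_kb_per_snp
        ):
            out.append((pos[a], pos[b], n_snp))
    return out


def random_toy_chromosome(rng: np.random.Generator, max_sites: int = 300):
    """Random marker geometry and genotypes, tuned so that runs of
    homozygosity of all fates (kept, too short, too sparse, gap-split)
    occur."""
    n = int(rng.integers(10, max_sites + 1))
    gaps = rng.choice(
        [500, 2000, 5000, 20_000, 150_000], size=n, p=[0.3, 0.3, 0.25, 0.1, 0.05]
    )
    pos = np.cumsum(gaps) + 1
    # blocks of mostly-homozygous and mixed calls
    g = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        block = int(rng.integers(5, 120))
        kind = rng.random()
        if kind < 0.5:  # ROH-like: rare hets/missing
            probs = [0.55, 0.02, 0.40, 0.03]
        elif kind < 0.8:  # heterozygous region
            probs = [0.3, 0.4, 0.25, 0.05]
        else:  # missing-heavy
            probs = [0.4, 0.1, 0.3, 0.2]
        g[i : i + block] = rng.choice(
            np.array([0, 1, 2, MISSING], dtype=np.int8),
            size=min(block, n - i),
            p=probs,
        )
        i += block
    return pos, g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
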