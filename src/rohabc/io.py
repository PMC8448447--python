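"""File formats: VCF genotype I/O and TSV/JSON result writers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .demography import GridPoint
from .roh import ROHSegment, ROHSpectrum
from .simdata import MISSING, GenotypeTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "load_genotypes",
    "freq_table_from_tsv",
    "freq_table_from_vcf",
    "geo_records_from_tsv",
    "segments_to_frame",
    "write_segments",
    "spectrum_to_dict",
    "write_spectrum",
    "read_spectrum",
    "grid_to_frame",
    "write_grid",
]

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    table: GenotypeTable, path: str | Path, per_chromosome: bool = False
) -> None:
    """Write a minimal VCFv4.2 with GT:GQ:DP (REF=A, ALT=C placeholders).

    With ``per_chromosome`` the path is treated as a template and one file
    per chromosome is written (``name.vcf`` -> ``name.chr1.vcf`` ...).
    """
    path = Path(path)
    if per_chromosome:
        for c in table.chromosomes():
            sub = table.take(table.chrom == c)
            write_vcf(sub, path.with_suffix(f".{c}{path.suffix}"))
        return
    contigs = {}
    for c in table.chromosomes():
        sel = table.chrom == c
        contigs[c] = int(table.pos[sel].max()) if sel.any() else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohabc\n")
        for c, L in contigs.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for i in range(table.n_sites):
            cells = [
                f"{_GT_STRING[int(table.gt[i, j])]}:{table.gq[i, j]}:{table.dp[i, j]}"
                for j in range(len(table.sample_ids))
            ]
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\tA\tC\t.\tPASS\t.\tGT:GQ:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a diploid VCF into a GenotypeTable (no filtering)."""
    return load_genotypes(path, min_gq=None, min_dp=None)[0]


def load_genotypes(
    path: str | Path, min_gq: float | None = 30, min_dp: float | None = 10
) -> tuple[GenotypeTable, dict[str, int]]:
    """Read a VCF, dropping sites where any sample fails the GQ/DP filters.

    Returns the table and drop counts. Thresholds of ``None`` disable a
    filter. Missing genotypes are kept as missing dosages.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    chroms, poss, gts, gqs, dps = [], [], [], [], []
    n_total = 0
    n_fail_gq = 0
    n_fail_dp = 0
    for v in vcf:
        n_total += 1
        gt = np.array(
            [_dosage(g) for g in v.genotypes], dtype=np.int8
        )
        gq = _format_field(v, "GQ", len(samples))
        dp = _format_field(v, "DP", len(samples))
        if min_gq is not None and (gq < min_gq).any():
            n_fail_gq += 1
            continue
        if min_dp is not None and (dp < min_dp).any():
            n_fail_dp += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        gts.append(gt)
        gqs.append(gq)
        dps.append(dp)
    table = GenotypeTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        gt=np.array(gts, dtype=np.int8).reshape(len(poss), len(samples)),
        gq=np.array(gqs, dtype=np.int32).reshape(len(poss), len(samples)),
        dp=np.array(dps, dtype=np.int32).reshape(len(poss), len(samples)),
        sample_ids=samples,
    )
    return table, {
        "sites_read": n_total,
        "dropped_gq": n_fail_gq,
        "dropped_dp": n_fail_dp,
        "sites_kept": table.n_sites,
    }


def _dosage(genotype) -> int:
    alleles = [a for a in genotype[:-1] if a is not None and a >= 0]
    if len(alleles) < 2:
        return MISSING
    return int(alleles[0] > 0) + int(alleles[1] > 0)


def _format_field(variant, name: str, n_samples: int) -> np.ndarray:
    arr = variant.format(name)
    if arr is None:
        return np.zeros(n_samples, dtype=np.int32)
    return np.asarray(arr, dtype=np.float64).reshape(n_samples, -1)[:, 0].astype(np.int32)


def freq_table_from_tsv(path: str | Path):
    """Read a FreqTable from TSV with columns CHR, POS and one frequency
    column per population."""
    from .fstats import FreqTable

    df = pd.read_csv(path, sep="\t")
    pops = [c for c in df.columns if c not in ("CHR", "POS")]
    return FreqTable(
        chrom=df["CHR"].to_numpy(dtype=object),
        pos=df["POS"].to_numpy(dtype=np.int64),
        freqs={p: df[p].to_numpy(dtype=float) for p in pops},
    )


def freq_table_from_vcf(path: str | Path, populations: dict[str, list[str]]):
    """Per-population derived-allele frequencies from a diploid VCF.

    ``populations`` maps population name -> member sample ids; missing
    dosages are treated as unobserved.
    """
    from .fstats import FreqTable

    table = read_vcf(path)
    freqs, counts = {}, {}
    for name, members in populations.items():
        cols = [table.sample_index(s) for s in members]
        g = table.gt[:, cols].astype(float)
        obs = g != MISSING
        n = 2 * obs.sum(axis=1)
        freqs[name] = np.where(obs, g, 0).sum(axis=1) / np.maximum(n, 1)
        counts[name] = np.maximum(n, 1)
    return FreqTable(chrom=table.chrom, pos=table.pos, freqs=freqs, counts=counts)


def geo_records_from_tsv(path: str | Path):
    """GeoRecords from TSV with columns INDIVIDUAL, F3, LAT, LON."""
    from .fstats import GeoRecord

    df = pd.read_csv(path, sep="\t")
    return [
        GeoRecord(str(r.INDIVIDUAL), float(r.F3), float(r.LAT), float(r.LON))
        for r in df.itertuples()
    ]


def segments_to_frame(segments: list[ROHSegment], sample: str) -> pd.DataFrame:
    """Segments as the de-facto .hom layout."""
    return pd.DataFrame(
        {
            "SAMPLE": sample,
            "CHR": [s.chromosome for s in segments],
            "BP1": [s.start_bp for s in segments],
            "BP2": [s.end_bp for s in segments],
            "NSNP": [s.n_snp for s in segments],
            "KB": [s.length_kb for s in segments],
        }
    )


def write_segments(segments: list[ROHSegment], sample: str, path: str | Path) -> None:
    segments_to_frame(segments, sample).to_csv(path, sep="\t", index=False)


def spectrum_to_dict(spectrum: ROHSpectrum) -> dict:
    return {
        "bin_edges_mb": list(spectrum.bin_edges_mb),
        "total_mb_per_bin": list(spectrum.total_mb_per_bin),
        "genome_fraction": spectrum.genome_fraction,
    }


def write_spectrum(spectrum: ROHSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(spectrum_to_dict(spectrum), fh, indent=2)
        fh.write("\n")


def read_spectrum(path: str | Path) -> ROHSpectrum:
    with open(path) as fh:
        d = json.load(fh)
    return ROHSpectrum(
        bin_edges_mb=tuple(d["bin_edges_mb"]),
        total_mb_per_bin=tuple(d["total_mb_per_bin"]),
        genome_fraction=d["genome_fraction"],
    )


def grid_to_frame(points: list[GridPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "N": [p.N for p in points],
            "T": [p.T for p in points],
            "n_accepted": [p.n_accepted for p in points],
            "likelihood": [p.likelihood for p in points],
            "log10_aBF": [p.log10_aBF for p in points],
        }
    )


def write_grid(points: list[GridPoint], path: str | Path) -> None:
    grid_to_frame(points).to_csv(path, sep="\t", index=False, na_rep="NA")
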