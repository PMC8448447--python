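"""Orchestration: structured config, seed streams, and the two-stage
(N, T) inference.

A single YAML config drives every stage; all randomness flows from one
master seed through named sub-streams. The inference runs a broad search on
a chromosome subset (by default chr3-22), narrows the grid to the
neighborhood of the broad-search optimum, and re-evaluates on the full
genome (chr1-22), writing both grids, the maximum-likelihood point with
decisiveness flags, and a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .demography import (
    COARSE_CHROMS,
    GridPoint,
    GridSpec,
    fit_grid,
    is_decisive,
)
from .io import load_genotypes, read_spectrum, write_grid, write_spectrum
from .roh import DEFAULT_BIN_EDGES_MB, ROHParams, ROHSpectrum, call_roh, compute_spectrum
from .simdata import ANCIENT_ID, DemographicScenario, GenomeLayout

log = logging.getLogger("rohabc")

__all__ = ["RunConfig", "run_inference", "stream_seed"]


def stream_seed(master_seed: int, name: str) -> int:
    """Named, reproducible sub-seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1) + 1


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML."""

    seed: int = 1
    scenario: DemographicScenario = field(default_factory=DemographicScenario)
    layout: GenomeLayout = field(default_factory=GenomeLayout)
    roh_params: ROHParams = field(default_factory=ROHParams)
    coarse_grid: GridSpec = field(default_factory=lambda: GridSpec(
        chromosome_subset=COARSE_CHROMS))
    final_grid: GridSpec | None = None  # derived from coarse MAP when absent
    bin_edges_mb: tuple[float, ...] = DEFAULT_BIN_EDGES_MB
    min_gq: float = 30.0
    min_dp: float = 10.0
    observed_vcf: str | None = None       # real data path, or
    observed_spectrum: str | None = None  # precomputed spectrum JSON, or
    observed_synthetic: bool = True       # simulate the observed genome
    panel_size: int = 10
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "scenario" in kwargs:
            sc = dict(kwargs["scenario"])
            if isinstance(sc.get("ooa_params"), dict):
                from .simdata import OOAScaffold

                sc["ooa_params"] = OOAScaffold(**sc["ooa_params"])
            kwargs["scenario"] = DemographicScenario(**sc)
        if "layout" in kwargs:
            lay = dict(kwargs["layout"])
            if "chromosomes" in lay:
                lay["chromosomes"] = tuple(
                    (str(c), int(L)) for c, L in lay["chromosomes"]
                )
            kwargs["layout"] = GenomeLayout(**lay)
        if "roh_params" in kwargs:
            kwargs["roh_params"] = ROHParams(**kwargs["roh_params"])
        for key in ("coarse_grid", "final_grid"):
            if kwargs.get(key) is not None:
                kwargs[key] = GridSpec(**kwargs[key])
        if "bin_edges_mb" in kwargs:
            kwargs["bin_edges_mb"] = tuple(kwargs["bin_edges_mb"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"]["chromosomes"] = [list(c) for c in d["layout"]["chromosomes"]]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _observed_segments(config: RunConfig):
    """ROH segments of the observed genome (real VCF or one synthetic
    simulation of the full layout). Returns (segments, sample_label)."""
    if config.observed_vcf:
        table, counts = load_genotypes(
            config.observed_vcf, min_gq=config.min_gq, min_dp=config.min_dp
        )
        log.info("loaded %s: %s", config.observed_vcf, counts)
        sample = table.sample_ids[0]
    elif config.observed_synthetic:
        from .simdata import ascertain_sites, simulate_scenario

        seed = stream_seed(config.seed, "observed")
        table = simulate_scenario(
            config.scenario, config.layout, config.panel_size, seed,
            recomb_cutoff_gen=config.coarse_grid.recomb_cutoff_gen,
            marker_fraction=config.coarse_grid.marker_fraction,
        )
        table = ascertain_sites(table, config.layout, seed)
        sample = ANCIENT_ID
    else:
        raise ValueError("no observed data source configured")
    return call_roh(table, sample, config.roh_params), sample


def _stage_spectrum(segments, layout: GenomeLayout, config: RunConfig) -> ROHSpectrum:
    names = {c for c, _ in layout.chromosomes}
    kept = [s for s in segments if s.chromosome in names]
    return compute_spectrum(kept, layout.total_bp, config.bin_edges_mb)


def _neighborhood(values: tuple[float, ...], best: float) -> tuple[float, ...]:
    """The best value and its immediate grid neighbors."""
    ordered = sorted(values)
    i = ordered.index(best)
    return tuple(ordered[max(0, i - 1): i + 2])


def run_inference(config: RunConfig) -> dict:
    """Two-stage grid inference; writes grids, best model, and a manifest.

    Returns a summary dict with the final-stage maximum-likelihood point.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    coarse_layout = config.layout
    if config.coarse_grid.chromosome_subset is not None:
        names = [c for c, _ in config.layout.chromosomes]
        subset = [c for c in config.coarse_grid.chromosome_subset if c in names]
        coarse_layout = config.layout.subset(subset) if subset else config.layout

    if config.observed_spectrum:
        observed = read_spectrum(config.observed_spectrum)
        segments = None
    else:
        segments, _ = _observed_segments(config)
        observed = _stage_spectrum(segments, coarse_layout, config)
    write_spectrum(observed, out / "observed_spectrum.json")

    log.info("coarse stage: %d x %d grid, %d reps/point",
             len(config.coarse_grid.N_values), len(config.coarse_grid.T_values),
             config.coarse_grid.replicates_per_point)
    coarse = replace(
        config.coarse_grid,
        seed=stream_seed(config.seed, "coarse"),
        chromosome_subset=None,  # already folded into coarse_layout
    )
    coarse_points = fit_grid(
        observed, config.scenario, coarse_layout, coarse, config.roh_params
    )
    write_grid(coarse_points, out / "coarse_grid.tsv")
    coarse_best = _map_point(coarse_points)
    log.info("coarse MAP: N=%g T=%g (L=%.3f)",
             coarse_best.N, coarse_best.T, coarse_best.likelihood)

    final_layout = config.layout
    if config.final_grid is not None:
        final = config.final_grid
        if final.chromosome_subset is not None:
            final_layout = config.layout.subset(final.chromosome_subset)
            final = replace(final, chromosome_subset=None)
    else:
        final = replace(
            config.coarse_grid,
            N_values=_neighborhood(config.coarse_grid.N_values, coarse_best.N),
            T_values=_neighborhood(config.coarse_grid.T_values, coarse_best.T),
            chromosome_subset=None,
        )
    final = replace(final, seed=stream_seed(config.seed, "final"))

    observed_final = observed
    if final_layout.chromosomes != coarse_layout.chromosomes:
        if segments is None:
            raise ValueError(
                "a precomputed observed spectrum cannot be re-binned for a "
                "different chromosome subset; supply a VCF or use a synthetic "
                "observed genome"
            )
        observed_final = _stage_spectrum(segments, final_layout, config)
        write_spectrum(observed_final, out / "observed_spectrum_full.json")

    log.info("final stage: %d x %d grid on %d chromosomes",
             len(final.N_values), len(final.T_values),
             len(final_layout.chromosomes))
    final_points = fit_grid(
        observed_final, config.scenario, final_layout, final, config.roh_params
    )
    write_grid(final_points, out / "final_grid.tsv")
    best = _map_point(final_points)

    summary = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "coarse_map": {"N": coarse_best.N, "T": coarse_best.T,
                       "likelihood": coarse_best.likelihood},
        "final_map": {"N": best.N, "T": best.T, "likelihood": best.likelihood,
                      "log10_aBF": best.log10_aBF},
        "decisive_against": [
            {"N": p.N, "T": p.T,
             "log10_aBF": None if p.aBF_is_na else p.log10_aBF}
            for p in final_points if p is not best and is_decisive(p.log10_aBF)
        ],
        "runtime_s": round(time.time() - t_start, 2),
    }
    with open(out / "best_model.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "seeds": {
            "master": config.seed,
            "observed": stream_seed(config.seed, "observed"),
            "coarse": stream_seed(config.seed, "coarse"),
            "final": stream_seed(config.seed, "final"),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    log.info("run complete in %.1fs; outputs in %s", summary["runtime_s"], out)
    return summary


def _map_point(points: list[GridPoint]) -> GridPoint:
    return next(p for p in points if p.is_map)
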