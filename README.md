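# rohabc

Demographic inference for ancient genomes from runs of homozygosity (ROH),
with the ancillary statistics an ancient-DNA population study needs.

A single ancient diploid genome carries a record of its population's
history in its ROH length spectrum: a lineage that stayed small for
millennia accumulates many *short* ROH (old coalescence), while recent
inbreeding produces few *long* ones. `rohabc` turns that record into an
estimate of the effective population size N and split time T of an
isolated lineage — the motivating case is the Jomon lineage of the
Japanese archipelago, isolated after the Last Glacial Maximum — by:

1. **Simulating** ancient diploid genomes under a three-population
   Out-of-Africa coalescent scaffold with an isolated branch (constant
   size N, split T years BP, one diploid sampled `sample_age` years BP)
   plus a modern ascertainment panel (msprime);
2. **Calling ROH** with the PLINK `--homozyg` sliding-window semantics at
   the standard ancient-genome parameterization (50-SNP windows, ≤1 het,
   ≥500 kb, ≥50 SNPs, 100-kb gap, 50 kb/SNP density), after GQ ≥ 30 /
   DP ≥ 10 site filters;
3. **Fitting** the observed 0.5–100 Mb ROH spectrum by rejection-ABC over
   an (N, T) grid — likelihood = acceptance rate at a pooled-quantile
   tolerance — and comparing models with log10 approximate Bayes factors
   (aBF = 0 at the optimum, NA where likelihood is 0, > 2 decisive);
4. plus **f-statistics** (outgroup f3, f4) with weighted block-jackknife
   errors, a Haversine drift-versus-distance regression, Ry molecular
   sexing, mtDNA contamination rates, and admixture-date conversion.

Who it is for: population geneticists who want a tested, reproducible,
fully synthetic-data-capable implementation of this inference recipe —
every stage runs on genomes the package simulates itself.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
(12 chromosomes × 5 Mb). Simulate an "observed" ancient genome under
(N = 1000, T = 20 ka) and call its ROH:

```bash
python analysis/01_simulate_observed.py
python analysis/02_call_roh.py
```

```
"sites_simulated": 23348,
"sites_ascertained": 13855,
"marker_density_per_bp": 0.00023091666666666668
...
5 ROH segments; total 8.77 Mb; genome fraction 0.1461
per-bin Mb: {0.5: 1.88, 1.0: 0.0, 2.0: 2.12, 4.0: 4.76, ...}
```

Read: of ~23k simulated variants, ~14k survive panel-MAF ascertainment and
thinning to the genome-wide marker density (~2.3×10⁻⁴/bp, the density of a
660k-SNP panel); the bottlenecked genome is ~15% ROH, concentrated in the
short-to-middle bins — the small-population signature. Then fit the grid
in two stages (broad search on a chromosome subset, refined neighbourhood
on the full miniature genome):

```bash
python analysis/03_fit_grid.py   # writes results/analysis/fit/
```

The run emits `coarse_grid.tsv` and `final_grid.tsv` with columns
(N, T, n_accepted, likelihood, log10_aBF), `best_model.json` with the MAP
point (its log10 aBF is exactly 0) and the models decisively rejected
(log10 aBF > 2 or NA), and a `manifest.json` from which the run can be
reproduced bit-for-bit. On miniature genomes the MAP lands on the
generating point or its grid neighbour along the known (N, T) drift ridge
(isolation drift ≈ duration / 2N).

QC and geography utilities:

```bash
python analysis/04_fstats_geography.py
python analysis/05_qc_dates.py
```

```
"sex_calls": {"ry_0.000": "female", "ry_0.050": "unassigned", "ry_0.100": "male"},
"kofun_reference_age_bp": 1348,
"admixture_dates_bp": { "northeast_asian_pulse": {..., "years_bp": 3448, "se_years": 825},
                        "east_asian_pulse":      {..., "years_bp": 1748, "se_years": 175} }
```

Read: 84 ± 33 generations before a reference sample with mean median date
1348 years BP converts to 3448 ± 825 years BP at 25 years/generation — a
Yayoi-period admixture pulse; 16 ± 7 generations to 1748 ± 175 years BP, a
Kofun-period pulse.

There is also a CLI mirroring the stages:

```bash
rohabc simulate --config cfg.yaml --out sim.vcf
rohabc callroh sim.vcf --out sim.hom.tsv
rohabc spectrum sim.hom.tsv --assayed-bp 60000000 --out spec.json
rohabc fit --observed spec.json --config cfg.yaml --out grid.tsv
rohabc qc --y-reads 100 --sex-reads 1000
rohabc run --config cfg.yaml        # end-to-end two-stage inference
```

## Layout

```
src/rohabc/      library: simdata, roh, demography, fstats, qc, io, pipeline, cli
analysis/        numbered desk-scale drivers (simulate → ROH → fit → f-stats → QC)
tests/           pytest suite incl. brute-force ROH oracle and recovery experiment
scripts/         acceptance.py
docs/methods.md  model, assumptions, parameter defaults, problem sizes, limitations
```
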