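# Methods

`rohabc` infers the demographic history of a long-isolated human lineage
from the runs-of-homozygosity (ROH) profile of a single ancient diploid
genome. The motivating system is the Jomon lineage of the Japanese
archipelago: an Initial-Jomon individual (median date 8819 years BP) whose
genome carries an unusually large total of short ROH, the signature of a
small effective population size maintained over many millennia rather than
of recent inbreeding. The package also bundles the bespoke side
computations such a study needs: f-statistics with block-jackknife errors,
a drift-versus-geographic-distance regression, Ry molecular sexing,
mitochondrial contamination rates, and admixture-date conversion.

Everything runs on synthetic data generated by the package itself; no
external genomes are required.

## Demographic model

The simulated world is a three-population Out-of-Africa (OOA) scaffold —
African, European, and East Asian branches — with an additional isolated
branch that splits from the East Asian lineage `T_split` years before
present and then evolves at a constant diploid effective size `N_iso` with
no subsequent gene flow. One diploid is sampled from the isolated branch
`sample_age` years BP (default 8819); a panel of modern East Asian diploids
(default 10) is sampled at present for allele-frequency ascertainment.

Scaffold defaults are the classic maximum-likelihood OOA parameterization:

| parameter | value |
|---|---|
| ancestral size | 7,300 diploids |
| modern African size | 12,300 (expansion 8,800 gen ago) |
| OOA bottleneck size | 2,100 (split 5,600 gen ago) |
| European founding size / growth | 1,000, 0.4%/gen |
| East Asian founding size / growth | 510, 0.55%/gen |
| EU–EAS split | 848 gen ago |
| migration (AFR–B, AFR–EU, AFR–EAS, EU–EAS) | 25, 3, 1.9, 9.6 ×10⁻⁵ |
| mutation rate | 2.35×10⁻⁸ /bp/gen |
| recombination rate | 1.0×10⁻⁸ /bp/gen (uniform) |
| generation time | 25 years |

All values are configurable (`OOAScaffold`, `DemographicScenario`). Ages in
years are converted to generations rounding half-up (8819 y → 353 gen).
Because the search grid allows split times up to 40 ka — older than the
EU–EAS divergence (21.2 ka at 25 y/gen) — the isolated branch attaches to
the ancestral Eurasian bottleneck population whenever `T_split` predates
that divergence.

Each autosome is an independent coalescent replicate (msprime). Two
performance options, both off-by-default in the generator but enabled in
the grid-fitting defaults, keep desk-scale fits cheap without biasing
single-site statistics:

- **Hybrid deep history** (`recomb_cutoff_gen`, default 2000 in `GridSpec`):
  recombination is simulated exactly up to the cutoff; remaining lineages
  then coalesce with recombination off. Marginal per-site genealogies are
  still exact draws from the model; only the long-range correlation of
  *deep* coalescence times is approximated. ROH structure is produced by
  recent coalescence (a segment of length L Mb corresponds to a TMRCA of
  roughly 1/(2 r L) ≈ 100/L generations at r = 10⁻⁸), so a cutoff deeper
  than every grid split time leaves the observable essentially untouched.
  The cutoff auto-extends to `T_split` + 100 gen when a scenario's split is
  deeper than the configured cutoff.
- **Marker thinning** (`marker_fraction`): mutations are emitted at
  `marker_fraction × μ`. By Poisson thinning this is *distributionally
  identical* to simulating at μ and discarding a uniform fraction of sites,
  which the ascertainment step would do anyway; it only removes the wasted
  work. The default grid value 0.2 keeps the post-ascertainment density
  safely above the target (≈60% headroom measured at the defaults).

## Ascertainment

Real analyses of this kind genotype the ancient sample at panel SNPs
(transversions, minor allele frequency ≥ 1%), ~660,027 sites genome-wide.
The generator emulates this with two steps: drop sites whose panel minor
allele frequency is below `maf_threshold` (default 0.01), then thin the
survivors uniformly at random to `target_snp_density` (default
660,027 / hg19 autosome length ≈ 2.29×10⁻⁴ per bp, held fixed for
miniature genomes so marker spacing stays realistic, ~4.4 kb). Transversion
filtering is emulated purely as density: for ROH calling what matters is
marker spacing, not mutational class. MAF ascertainment matters
scientifically: variants private to the isolated branch are absent from the
panel and vanish, deflating the ancient sample's observed heterozygosity
exactly as in real array-ascertained data.

Synthetic calls carry GQ 99 / DP 30; `degrade_calls` can inject missingness
and het→hom errors for robustness experiments.

## ROH calling

`call_roh` reimplements the documented PLINK `--homozyg` semantics with the
printed flag set (window 50 SNPs, ≤1 het, ≤5 missing per window; a site is
in a run when ≥5% of covering windows accept; runs split at >100 kb
inter-marker gaps; kept when ≥50 SNPs, ≥500 kb, and ≤50 kb/SNP).
`window_missing = 5` is the tool default (the study lists only non-default
flags). Coordinates are 1-based inclusive; segment length is
`end − start + 1` bp. Correctness is pinned by a brute-force
window-enumeration oracle on random toy chromosomes (50 randomized cases in
the test suite), plus monotonicity (adding a het never lengthens a
segment) and per-chromosome independence properties.

The spectrum bins each in-range segment's full length into half-open bins
over {0.5, 1, 2, 4, 8, 16, 32, 100} Mb (top bin closed; edges configurable
— the canonical hunter-gatherer comparisons use log-spaced classes).
Segments outside 0.5–100 Mb stay in the segment list but not the spectrum.
`genome_fraction` is total in-range ROH bp over assayed bp.

## Rejection-ABC grid and approximate Bayes factors

For each grid point (N, T) the full forward pipeline (simulate →
ascertain → call ROH → bin) is replicated with deterministic per-replicate
seeds derived from (master seed, N, T, replicate). The summary distance is
the unweighted Euclidean norm of per-bin total-Mb differences (a
per-bin-scaled variant sits behind `scale_bins`). One tolerance ε — the
`acceptance_quantile` (default 5%) of distances pooled across the entire
grid — defines acceptance; the approximate likelihood of a point is the
fraction of its own replicates with distance ≤ ε. This pooled-quantile
rejection rule keeps likelihoods comparable across points while
guaranteeing a non-degenerate acceptance set.

Model choice uses log10 approximate Bayes factors against the
maximum-likelihood point: `log10 aBF(θ) = log10(L(θ*) / L(θ))`, 0 at the
optimum, NA where L = 0 (not measurable; treated as infinitely
disfavoured), and `> 2.0` (strict) read as decisive. Ties at the maximum
are broken to the smallest N then smallest T, logged, and flagged via
`is_map`; a tied runner-up still evaluates to aBF = 0, the mathematically
honest value.

The two-stage search mirrors the intended workflow: a broad grid on a
chromosome subset (default chr3–22), then a refined grid — by default the
one-step neighbourhood of the broad optimum — on the full genome
(chr1–22). Both stages share ROH parameters and bin edges; the observed
genome is realized once and re-binned per stage.

### The (N, T) ridge

Isolation-phase drift scales roughly with duration/(2N), so scenarios along
the diagonal (500, 10 ka) ~ (1000, 20 ka) ~ (2500, 40 ka) produce
near-equivalent ROH spectra; distinguishing along the ridge requires the
spectrum *shape* resolution of a full-size genome. Parameter-recovery
claims therefore count the truth or any grid neighbour (one step on each
axis, diagonals included) as success, matching how aBF balloon plots are
read.

## Problem sizes

Desk-scale configurations used by the test suite and acceptance script
(the package's own choices; each documents what it preserves):

- **Parameter recovery**: truth (N=1000, T=20 ka), genome 12 × 5 Mb, grid
  {500, 1000, 2500} × {10, 20, 40} ka, 20 replicates/point, 10 independent
  trials; success = MAP at truth or a grid neighbour in ≥ 8/10 trials.
- **Bottleneck signal**: 4 × 5 Mb genome, 100 replicates/point (60 in the
  faster acceptance script), one-sided Wilcoxon rank-sum on total ROH,
  N=2500 vs N=500 at T=20 ka.
- **Two-stage demo** (`analysis/03_fit_grid.py`): 12 × 5 Mb, coarse stage
  on chr3–12, refined neighbourhood on the full miniature genome.

At these sizes an ROH spectrum replicate costs ~25 ms per 5-Mb chromosome.

## f-statistics

`outgroup_f3(O; A, B)` is the site mean of (o−a)(o−b); `f4(A, B; C, D)` the
site mean of (a−b)(c−d). No small-sample heterozygosity correction is
applied to f3: in the outgroup use-case the correction is common to all
compared pairs and cancels. Standard errors use a weighted delete-one block
jackknife over contiguous physical windows (default 5 Mb — a stand-in for
the conventional 0.05-Morgan blocks, since synthetic data carries no
genetic map) with Busing-style weighting by per-block site counts; for
equal blocks this reduces to the ordinary delete-one jackknife, and for two
equal blocks to SE = |mean(b₁) − mean(b₂)|/2, which the tests verify by
hand.

`drift_distance_test` regresses per-individual shared drift (outgroup f3
with a target individual) on great-circle (Haversine, radius 6371 km)
distance from an origin, reporting the OLS slope with a two-sided t-test
and Pearson's r. The choice of test for the published correlation is not
documented; OLS-plus-Pearson is the conventional default and is stated as
such rather than as a reproduction.

## QC utilities

- **Ry sexing**: Ry = Y reads / (X+Y) reads; female if Ry < 0.016, male if
  Ry > 0.075; the open interval [0.016, 0.075] is returned `unassigned`
  (the published rule names only the two calling thresholds).
- **mtDNA contamination**: pooled (not per-site-averaged) rate of
  non-consensus bases over haplotype-defining and private sites; the
  damage-robust variant drops a site when its consensus base *or* any
  observed mismatch base is C or G (both-sided deamination rule;
  configurable in interpretation, documented here).
- **Date conversion**: years BP = reference age + generations × 25;
  SE scales the same way; affine and exactly invertible. The reference age
  is the mean of median calibrated dates rounded half-up (1378, 1340,
  1325 → 1348).

## What the synthetic data does and does not show

The generator reproduces: time-stamped ancient sampling, bottleneck-driven
ROH spectra, panel-based MAF ascertainment at realistic marker density,
passing-quality genotype annotations, and (optionally) missingness and
het-miscall noise. It does not model: sequencing reads or post-mortem
damage (UDG treatment and transversion filtering are assumed to have
handled damage upstream), a variable recombination map, selection, gene
flow into the isolated branch, or reference-bias effects. Passing tests
demonstrate the statistical machinery is correct and self-consistent under
the stated model — not that the model captures every property of real
ancient genomes, and the real-data headline quantities (the published
N≈1000 / T≈20 ka fit itself, specific f3 values, the admixture fraction)
require the original genomes and are out of scope by design.

## Numerical choices and edge cases

- All randomness flows from explicit integer seeds; per-chromosome and
  per-replicate seeds derive via `numpy.random.SeedSequence`, and pipeline
  stages use SHA-256-derived named streams. Seeds stay below 2³¹.
- Pooled tolerance uses `numpy.quantile` (linear interpolation); with n
  pooled distances the 5% quantile accepts ⌈0.05 n⌉-ish replicates — the
  discreteness is asserted, not hidden.
- Chromosomes with fewer sites than one window yield no segments; unsorted
  input is rejected; an empty ascertainment result warns but is legal.
- A grid where nothing is accepted anywhere raises "no model fits at this
  tolerance" rather than returning all-zero likelihoods.
- `spectrum_distance` refuses mismatched bin edges; `compute_spectrum`
  refuses non-positive assayed lengths and non-increasing edges.
- Dosage collisions from discretizing mutation positions to integer bp are
  dropped (first occurrence kept) — rare at the default density.

## Known limitations

- The hybrid deep-history approximation slightly distorts long-range
  linkage of deep TMRCA segments; observed and simulated genomes share the
  approximation, so grid inference is internally consistent.
- Likelihood granularity is 1/replicates; small desk-scale grids can tie,
  resolved by the deterministic tie-break.
- The miniature genome truncates the long-ROH tail (no segment can exceed
  the 5-Mb chromosome length), compressing the upper spectrum bins; all
  compared spectra share the truncation.
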