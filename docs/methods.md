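# Methods

This note records the statistical methods implemented in `migtime`, their
conventions, and the deliberate modelling choices. Code references are to
modules under `src/migtime/`.

## Synthetic cohorts (`simulate.py`)

Cohorts are generated under the Balding–Nichols model: each locus draws an
ancestral frequency `p ~ U(0.05, 0.95)` and per-population frequencies from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has mean `p` and variance
`F·p(1−p)`, so `background_fst` is the expected Wright fixation index
between populations. Genotypes are `Binomial(2, p_pop)` draws.

An optional 2 Mb "sweep" region supports two modes:

- **phenotype mode** — sweep loci track a latent haplotype shared across
  populations. Each individual carries two haplotype indicators
  (`Bernoulli(sweep_hap_freq)` per copy); a swept copy is the ALT allele at
  every sweep locus minus a small flip rate (near-monomorphic haplotype),
  while an ancestral copy segregates at the locus-specific ancestral
  frequency. This produces tight local LD, a strong allele-frequency
  contrast between carriers and non-carriers, and reduced within-group
  diversity among carrier-enriched individuals — the classic partial-sweep
  signature. Carriers get an earlier arrival phenotype (the haplotype's
  genetic-value component enters with a negative sign).
- **population mode** — sweep loci are drawn at `sweep_fst` differentiation
  between populations but are unlinked to the phenotype; additionally the
  early (lowest-latitude) population's sweep-locus minor-allele frequencies
  are shrunk by `sweep_diversity_factor`. This is the structure-only
  control.

The arrival phenotype is
`baseline + cline_slope·(lat − mean lat) + covariates + g + ε`, where the
genetic value `g` combines sparse causal effects, an infinitesimal polygenic
term and (in phenotype mode) the sweep-haplotype effect, standardized and
mixed by configured variance shares. `g` and `ε` are rescaled (with the
noise residualized against `g`) so the realized `var(g)/(var(g)+var(ε))`
equals `target_pve` exactly, not just in expectation. Causal loci are drawn
outside the sweep region from loci that are complete in the pre-masking
matrix. Missing genotypes are masked completely at random at
`missing_rate`. Output is plain-text VCF 4.2 + phenotype TSV + gene BED +
provenance JSON, reproducible from one seed.

## Geolocation (`geolocate.py`)

Threshold light-level geolocation from daily twilight pairs. Solar
declination and the equation of time use the Spencer (1971) truncated
Fourier series (declination error < 0.5°, equation-of-time error < 1 min).
Longitude is `15°/h × (12:00 UTC − EoT − twilight midpoint)`. Latitude is
the root of the sunrise equation (at a configurable sun-elevation threshold,
civil twilight −6° by default) matching the observed day length, found by
bisection on a 0.5° grid plus Brent refinement. Near the equinoxes the
day-length/latitude relation flattens and a spurious second root appears at
high latitude; root selection uses a continuity hint (the previous day's
estimate, optionally seeded by `initial_lat_hint`), and days where the local
sensitivity |d(day length)/d(lat)| falls below 4 min/deg are flagged
`equinox_unreliable` rather than interpolated. Arrival at a colony is the
first day of `persistence_days` consecutive ok-quality days within
`radius_km` (haversine) of the colony. A twilight simulator (the exact
inverse model plus optional Gaussian timing noise) supports closed-loop
tests.

## Variant QC (`qc.py`)

Filters run in a fixed order — biallelic, QUAL > 20, MQ > 20, per-site
missingness ≤ 0.20, MAF > 0.05 (strict: a site at exactly 0.05 is removed),
exact HWE p ≥ 1e−6 — and the report attributes each removed variant to the
first stage it fails. Each criterion is a property of the raw site, so the
surviving set is order-independent; only the attribution depends on order.
Records without an MQ value fail the MQ filter (missing evidence is not a
pass).

The HWE test is the two-sided exact test conditioning on the observed allele
counts: the p-value sums the probabilities of all heterozygote counts (same
parity and allele totals) no more probable than the observed one. It is
computed in log space with a relative tie tolerance of 1e−12. Being exact
and discrete, its null p-values are conservative at small sample sizes and
only approach uniformity for large per-site n.

Missing dosages are mean-imputed (2 × alt frequency of non-missing calls),
which preserves per-variant allele frequencies and column means exactly — a
deterministic, LD-free stand-in adequate for the downstream linear models.

## BSLMM (`bslmm.py`)

Bayesian sparse linear mixed model `y = Wα + Xβ + u + ε` with
`u ~ N(0, σ_b² K)`, `K` the centered GRM `X_c X_cᵀ / p`, sparse effects
`β_j ~ π N(0, σ_a²) + (1−π) δ₀`, and hyperpriors on `(h, ρ, log π)`:
`h, ρ ~ U(0,1)` and `log π ~ U(log(1/p), log(min(1, 300/p)))` — the upper
cap bounds the expected number of sparse effects at 300, which both matches
desk-scale sparsity and suppresses a degenerate many-tiny-effects mode of
the sampler. The variance scales are tied to `(h, ρ)` the conventional way:
`σ_a² = hρσ_e² / ((1−h)·max(πp,1)·v̄)` and
`σ_b² = h(1−ρ)σ_e² / ((1−h)·k̄)`, with `v̄` the mean per-SNP variance and
`k̄ = tr(K)/n`.

Sampling: covariates are projected out by QR (flat prior on α); per-SNP
spike-slab Gibbs sweeps run in a compiled kernel; `(logit h, logit ρ,
log π)` move by a joint random-walk Metropolis step whose target integrates
`u` out analytically in the eigenbasis of `K` (degenerate eigenvalues of the
centered GRM are excluded); `u` is then drawn exactly and `σ_e²` has its
conjugate update. Four chains with different starting points are
concatenated; a split-chain R-hat on the PVE samples is reported. PVE per
sample is `var(Xβ + u) / (var(Xβ + u) + σ_e²)`; the summary is the
posterior median and an 89% equal-tailed interval. Per-SNP posterior
inclusion probabilities (PIPs) are the retained-sample inclusion
frequencies.

Known information limit: with p ≫ n unlinked loci, the GRM eigenspectrum is
nearly flat, so `h` (and hence PVE) is only weakly identified; the posterior
can sustain tens of chance SNPs on permuted phenotypes. This is a property
of the model at these dimensions, not of the implementation (verified
against long reference chains); see the test suite's BSLMM acceptance tests,
which assert the stated targets and document where they are not attainable.

## Polygenic scores (`pgs.py`)

Clumping + thresholding. Marginal GWAS residualizes the phenotype and each
dosage on the covariates, then per-SNP OLS with t-based p-values. Greedy
p-value-ordered clumping keeps a variant unless an already-kept index on the
same scaffold within 250 kb has squared dosage correlation > 0.1. The
p-value threshold is chosen from a fixed ladder by incremental R² on an
internal 20% holdout of the training fold; weights are then refit on the
full training fold. Incremental R² is the squared correlation between the
score and the covariate-residualized phenotype.

Cross-validation is a 100-repetition jackknife with random 85/15
train/test splits: the model (GWAS, clumping, threshold search) is fit
entirely inside each training fold; held-out scores are standardized by the
training-fold score distribution; per-individual predicted scores are
averaged over the repetitions in which the individual was held out. Decile
summaries bin individuals by mean held-out score and report mean arrival
date per decile.

## Window scans (`scan.py`)

Weir & Cockerham (1984) F_ST with the two-group variance components
(a, b, c) per site and ratio-of-sums aggregation within windows
(`Σa / Σ(a+b+c)`), which is the standard weighting and is robust to
low-information sites. Phenotype-contrast groups are the k earliest vs k
latest arrivals; the structural contrast is southernmost vs northernmost
population. ΔF_ST is the per-window difference (phenotype-contrast minus
population-contrast), retaining negative values.

π is the per-site unbiased expected heterozygosity `2p(1−p)·2m/(2m−1)` over
the m genotyped diploids, summed over variant sites and divided by window
span (invariant positions contribute length only). Tajima's D uses the 1989
constants with the haploid sample size taken as `2 × round(mean m)` over the
window's segregating sites (missingness-aware); windows without segregating
sites are invalid rather than zero.

Region calling uses a robust Z-score `(v − median) / (1.4826·MAD)` over
valid windows, outliers at Z > 4, runs merged across gaps of ≤ 2 windows,
and a minimum of 2 outlier windows per region — isolated single-window
spikes are expected under the heteroskedastic noise of ratio-of-sums F_ST
and are not called. Gene overlap is ≥ 1 bp against a BED annotation with
half-open intervals.

## Pipeline (`pipeline.py`, `cli.py`)

One global seed is fanned out to per-stage seeds via
`numpy.random.SeedSequence(seed).spawn(...)` in a fixed stage order, so a
single number reproduces a full run byte for byte. Every defaulted
parameter is echoed into `report.json`. Stages: simulate → QC → BSLMM →
PGS → scans (each stage optional, with external VCF/phenotype inputs
supported). The CLI exposes `simulate`, `qc`, `geolocate`, `run` (YAML
config) and `run-default`.
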