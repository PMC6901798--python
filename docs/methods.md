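# Methods

This note documents the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Value spaces

Array methylation is measured as beta values β ∈ [0, 1]. All modelling is
done on M-values, M = log2(β/(1−β)), because (a) M-values are unbounded, so
additive group effects and additive batch effects are coherent, and (b)
tumor-vs-normal effect sizes above 1 on the logFC scale are impossible as
beta differences but routine as M differences. The logit transform clips
beta into [ε, 1−ε] with ε = 1e−6; the inverse transform is exact to well
below 1e−12 inside that range. `logFC` throughout means the tumor−normal
difference of M-value group means.

## Batch adjustment

Cross-cohort batch effects are removed per probe by mean centering within
batch with grand-mean restoration: x′_gi = x_gi − mean_g(batch(i)) +
grandmean_g. This is exactly what a gene-wise one-way ANOVA adjustment
removes; it is idempotent, preserves each probe's grand mean exactly, and
zeroes the between-batch sum of squares. Variance rescaling and
empirical-Bayes batch models (ComBat-style) are deliberately out of scope:
the additive location shift is the only batch structure the pipeline
assumes, and the generator plants exactly that structure. Adjustment is
applied in M-space; adjusting beta values directly can leave the unit
interval and is rejected by the container validation.

## Moderated t differential methylation

Per probe, a two-group linear model gives logFC_g, the pooled residual
variance s²_g on d_g = n_t + n_n − 2 degrees of freedom, and v_g = 1/n_t +
1/n_n. The variance prior (d₀, s₀²) is estimated by the method of moments on
z_g = log s²_g: with e_g = z_g − ψ(d_g/2) + log(d_g/2), the excess of the
empirical variance of e over the sampling term mean ψ′(d_g/2) equals
ψ′(d₀/2), solved by monotone root finding (ψ′ is strictly decreasing;
Brent's method on [1e−10, 1e10]); s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). A
non-positive excess collapses to d₀ = ∞ with s₀² = exp(ē) (the same limit of
the finite formula). Zero-variance probes are excluded from the moment fit
but still shrunk by the resulting prior; if every probe has zero variance
the estimate is refused rather than silently degenerate. The moderated
statistic t_g = logFC_g/√(s̃²_g·v_g) is referred to t(d₀ + d_g), with the
degrees of freedom capped at 1e6 where the t distribution is numerically
normal. This estimator agrees with the Bioconductor reference implementation
to machine precision on simulated data (see the cross-check test), and on a
5,000-probe scaled-chi-square simulation recovers d₀ within ±25% and s₀²
within ±10%.

Multiple testing uses Benjamini–Hochberg step-up, and DMPs are called at
|logFC| > 1 with adjusted p < 0.05. The adjustment procedure behind the
published "adjusted p" is not named in the source material; BH is the field
default. Ties in the output ordering are broken by |logFC| descending, then
probe id, so tables are deterministic.

## Binarization

K-means with k = 2 in one dimension has a closed-form global optimum:
clusters are contiguous in sorted order, so the best of the n−1 sorted
splits by total within-cluster sum of squares is *the* 2-means solution.
Using it instead of Lloyd iterations removes all seed sensitivity. Ties are
broken toward the larger low cluster; the decision threshold is the midpoint
between the largest low-cluster and smallest high-cluster value; the
higher-mean cluster is coded 1. Constant probes cannot be split and are
dropped with a record, never silently. On a validation cohort the splits are
recomputed from that cohort's own values — the protocol's answer to
cross-platform and cross-batch location shifts — rather than reusing
training thresholds.

A practical regime note: per-probe 2-means identifies the tumor/normal
structure only when the within-class spread is clearly below the class
separation. Under heavy imbalance with wide within-class spread the optimal
split cuts the majority cloud instead of the class gap. Real bimodal array
data at strong marker CpGs is in the well-separated regime, and the
validation scenario is generated in it.

## Panel selection

Ranking is by recursive feature elimination over seeded random forests
(500 trees): each round fits the forest on a stratified 75% of samples,
scores features by permutation importance on the held-out 25% (permutation
importance is used because impurity importance is biased for correlated
binary features; a held-out split stands in for out-of-bag scoring, which
scikit-learn does not expose per forest), and eliminates the weakest
⌈20% of remaining⌉. The final rank is the reverse elimination order with
within-round ties broken by importance then probe id.

The greedy build walks the ranking, always admits the first probe, and
admits a later probe only if its maximum absolute phi coefficient against
the current panel is below 0.7 (phi — Pearson on 0/1 vectors — because
selection operates in the binarized space). After each admission the prefix
is scored by stratified 10-fold cross-validation (stratified so that the
minority class cannot vanish from a fold under imbalance; folds are reduced
with a warning if the minority class is smaller than the fold count);
pooled out-of-fold predictions are scored once for accuracy and Cohen's
kappa. The final prefix maximizes accuracy with kappa as tie-break and
smaller size as final tie-break ("best accuracy and kappa" is ambiguous when
the two disagree; accuracy-primary is the documented reading). The whole
selection is a pure function of (features, labels, seed).

## Imbalance-corrected validation

The validation protocol is: re-binarize the panel probes on the new cohort,
hold out a stratified 20% test set, rebalance only the training portion by
smoothed bootstrap, retrain the forest, and score the untouched test set
with tumor as the positive class. Rebalancing is top-up oversampling of the
minority class: every real sample is kept, and synthetic minority samples —
a uniformly drawn minority row plus independent Gaussian noise with
per-feature bandwidth h_q = (4/((d+2)·n_j))^(1/(d+4))·σ_jq computed from the
minority class — are appended until the classes are exactly balanced.
Because the kernel produces continuous values in a binary feature space,
synthetic rows are thresholded at 0.5 back to {0, 1} so training and test
spaces match (feeding continuous values is available behind a flag). A
single-sample minority class with zero variance falls back to exact
duplication with a warning. Cohen's kappa is computed from the confusion
matrix marginals, κ = (p_o − p_e)/(1 − p_e), and flagged undefined when
p_e = 1.

## Synthetic cohorts

The generator emulates what the analysis assumes and nothing more: bimodal
beta baselines at two modes (default 0.15/0.85); additive M-space tumor
shifts of magnitude `effect_m` at `n_signal_blocks` blocks of `block_size`
redundant probes (signs alternate per block); a per-(block, sample) shared
latent with sd `shared_noise_m` that gives probes of a block their common
signal beyond the label; independent per-probe jitter (`within_block_noise_m`);
additive per-(batch, probe) shifts (`batch_sd_m`) with round-robin batch
labels; and Beta-distributed measurement noise with concentration
`precision`. Signal probes start at the baseline mode their shift departs
from (hypermethylation leaves the unmethylated mode), which keeps the
shifted class away from the beta boundary where logit-scale noise is
amplified. One seeded generator stream drives the whole cohort.

The **documented recovery scenario** (160 tumors / 40 normals, 4 blocks of 5
probes, 500 null probes, effect 3.0, shared latent 1.8, precision 300, two
batches of sd 0.4, seed 1281) is engineered so that (a) every within-block
probe pair stays above the 0.7 redundancy cutoff after binarization while
every cross-block pair stays clearly below it (same-sign block pairs sit
near phi ≈ 0.2–0.3; the all-pairs population value ~0.2 carries a sampling
sd of ~0.07 at n = 200, which is why the invariant is asserted as min-intra
> 0.7, mean-inter < 0.3, max-inter < 0.55), and (b) each block's binarized
probes agree with the tumor label only ~77–80% of the time, so no small
subset of blocks suffices and the cross-validated accuracy climbs to ~96%
only at the full four-block panel. Because four conditionally independent
binary markers under an 80% class prior put the 2-, 3- and 4-feature CV
accuracies within a few points of each other, the argmax panel size is
sensitive to fold noise; the recovery property is therefore stated — and
tested — for the documented seeds, and the acceptance script runs discovery
under exactly those documented seeds while varying the validation split and
rebalancing with its `--seed`.

The **validation scenario** keeps the planted blocks but uses the 458/34
class shape of a large validation series and a smaller shared latent (0.8):
a single-series cohort has no reason to carry the discovery design's extra
within-class spread (which exists only to keep blocks mutually
non-redundant), and the smaller spread puts the 2-means splits in the
well-separated regime described above (per-probe label agreement ≈ 0.95).
Validation accuracy there is ~95–100% with kappa ~0.7–1.0 across seeds.

What the synthetic cohorts do **not** model: Infinium I/II probe-type
chemistry, sex chromosomes, copy-number contamination, cell-type
composition, probe-specific noise scales, and any correlation between null
probes. Passing tests demonstrate that the pipeline's machinery recovers
planted structure under its own assumptions — not that those assumptions
hold on any particular real array series. No noise model was available to
estimate from the source data; the generator's defaults are conventions
chosen to look like tumor/normal 27k arrays, fixed once.

## Numerical and degenerate-input policy

Matrix containers validate value ranges, duplicate identifiers and
non-finite entries at construction. Missing values are rejected, not
imputed. Constant probes: dropped (binarization), zero-variance but shrunk
(moderation), error (phi coefficient). BH refuses p-values outside [0, 1].
Splits guarantee at least one sample of each class on both sides. All
stochastic steps take explicit integer seeds; pipeline stage seeds are
derived from one master seed as crc32("{seed}:{stage}") & 0x7fffffff, and a
rerun of the same configuration writes byte-identical artifacts.

## Problem sizes

Defaults used by the test suite and acceptance script: discovery 520 probes
× 200 samples; validation 520 × 492; null calibration 2,000 probes × 60
samples × 20 replicates; moderation recovery 5,000 probes; oracle
equivalence 500 random cases per algorithm. These sizes make every property
statistically decidable while keeping the full suite to a few minutes on a
single CPU.

## Known limitations

* CV performance of the selected prefix is an in-sample model-selection
  quantity, not an unbiased generalization estimate (no nested CV — the
  protocol being reproduced did not use one).
* The greedy correlation filter is order-dependent by construction; a probe
  skipped early is never reconsidered.
* The moderated test assumes a common variance prior across probes; strong
  variance strata (e.g. probe-type effects) would call for a trend term,
  which is out of scope.
* `run-all` byte-identity holds for the package's own TSV/JSON writers; it
  is not guaranteed across numpy/scikit-learn major versions.
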