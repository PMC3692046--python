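# Methods

This note documents the statistical procedures implemented in tmakit, the
choices made where the design was genuinely open, and what the synthetic
cohorts used in testing do and do not establish about real tissue-microarray
(TMA) data.

## Data model

A TMA dataset is a samples × markers grid of expression scores (continuous
AQUA-style scores or semi-continuous/categorical quickscores), optionally
with replicate columns (identical column names), a `*Batch` column naming
the TMA block each sample was processed on, `*cov`-prefixed covariate
columns, and a separate survival table (id, follow-up time in months, event
indicator; 1 = event, 0 = right-censored). Missing cells ("", "NA", "NaN",
case-insensitive) are carried as NaN throughout; a marker is categorical
when its non-missing values are integers on at most 10 distinct levels
(overridable). Scores, survival tables and networks round-trip through
CSV/TSV/XLSX, CSV and GraphML respectively.

Replicate columns are combined by the mean (configurable to median) of the
non-missing replicate values. When batch correction is requested it runs
*before* replicate collapse, because block-to-block effects act on each
stained column separately; without batch correction, collapse happens
before analysis.

## Batch-effect reduction

Batch effects are removed with a parametric empirical-Bayes location/scale
model. For marker g, sample s in batch b:

    y_sg = alpha_g + X_s beta_g + gamma_bg + delta_bg * eps_sg,  eps ~ N(0, sigma_g^2)

Per marker, alpha, beta and sigma are estimated by least squares on the
batch-indicator + covariate design (a covariate collinear with the batch
design is reported by name and rejected), and scores are standardised.
Across markers, batchwise method-of-moments hyperpriors are fitted — a
normal prior on the additive effects gamma and an inverse-gamma prior on
the squared multiplicative effects delta² — and the conditional posterior
means gamma*, delta* are iterated to convergence (max-abs change < 1e-6,
at most 500 iterations). The corrected score is
sigma_g·(z_sg − gamma*_bg)/delta*_bg + alpha_g + X_s beta_g.

Two adaptations make this workable on TMA grids, which are small and
unevenly missing:

* every sum is taken over observed cells only (pairwise-complete), and
* a screening pass first removes any marker/replicate column that, within
  some batch, has fewer than 2 non-missing values or zero variance
  (reason codes `insufficient_in_batch`, `zero_variance_in_batch`).
  These thresholds are this package's concrete definition of a
  "problematic" column; they are the minimum that keeps the per-batch
  variance estimates defined.

With a single marker (or a degenerate across-marker spread) there is no
cross-marker information to shrink with, and the per-batch estimates are
used unshrunk. Shrinkage pulls each batch's effects toward the across-marker
batch average, so the corrected pooled mean can move slightly when batch
effects differ strongly across markers; the per-marker pooled mean is
preserved up to this shrinkage effect.

## Distribution exploration

Continuous markers get two complementary summaries.

**Adaptive KDE.** A Gaussian-kernel pilot estimate at Silverman's
rule-of-thumb bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5) supplies local
bandwidths by Abramson's square-root law, λ_i ∝ pilot(x_i)^(−1/2)
normalised to geometric mean 1, giving sharper peaks and smoother tails
than a fixed bandwidth. The evaluation grid spans the data range ± 3 pilot
bandwidths; the trapezoidal integral is checked to lie in [0.99, 1.01].

**Gaussian mixtures with BIC.** Mixtures with independent per-component
means and SDs are fitted by EM (convergence: log-likelihood change < 1e-8,
max 1000 iterations; component variance floored at 1e-6 × data variance to
prevent singular collapse). Each K uses the best of 10 restarts: the first
initialised by slicing the sorted data into K quantile blocks, the rest by
seeded random responsibilities. EM runs on the sorted values so results are
invariant to sample order. K = 1..min(9, n/4) are compared by
BIC = −2·logL + (3K−1)·ln n (smaller is better; ties go to smaller K).
Samples are assigned to the MAP component; components are mean-ordered so
label 0 is always the lowest-expressing group, and exact ties go to the
lower-mean component. Categorical markers take a histogram path and are
never mixed or density-estimated. A K = 1 (unimodal) outcome is flagged so
survival analysis falls back to tertiles.

The EM inner loop is compiled with numba; the pure-numpy `_em` implements
the same updates and backs the monotonicity test.

## Survival analysis

The survival function is the Kaplan–Meier product-limit estimator; ties
between events and censorings at the same time count the events first
(censored subjects leave the risk set after their time). Group differences
are tested with the Mantel-Cox log-rank statistic: at each distinct event
time the observed events per group are compared with their hypergeometric
expectation, the statistic is (O−E)ᵀV⁻¹(O−E) with one group dropped so the
covariance is invertible, and the reference distribution is chi-square with
(groups − 1) degrees of freedom.

Stratification modes per marker:

* **mixture** — MAP labels of the BIC-selected mixture; refused with a
  tertile hint when the model is unimodal;
* **tertile** — thirds at the 1/3 and 2/3 empirical quantiles (linear
  interpolation; boundary ties go to the lower group);
* **categorical** — one group per observed score level.

A screen stratifies and tests every marker, then applies Benjamini–Hochberg
FDR across the markers actually tested — markers refused by their
stratifier are excluded from the BH universe m and reported separately.

## Network inference

All C(M,2) marker pairs are scored on pairwise-complete observations
(listwise deletion would waste scarce TMA samples); n per pair is recorded.
Pairs refused for insufficient data (n < 4 for correlations, n < 8 for
mutual information) or zero variance are excluded from the adjustment
universe. All p-values are two-sided (doubled one-sided tail, capped at 1).

* **Spearman** rho on mid-ranks. Significance is regime-dependent: exact
  permutation null for n ≤ 9 without ties (computed by a dynamic program
  over rank subsets that reproduces the full n! distribution of
  S = Σd²); the AS 89 Edgeworth tail approximation for 10 ≤ n < 1290
  without ties; Student-t otherwise (ties invalidate the exact/AS89 null).
  The regime used is recorded per edge.
* **Pearson** r with t = r√((n−2)/(1−r²)) on n−2 df.
* **Mutual information** (nats) after equal-frequency binning into
  B = clamp(⌊√n⌋, 2, 10) bins (categorical markers keep native levels),
  with p = (1 + #{perm ≥ obs})/(1 + n_perm) over seeded permutations.
  MI edges are unsigned (sign = 0).

Adjustment methods: Benjamini–Yekutieli (step-up with the harmonic factor
c(m) = Σ 1/i; valid under arbitrary dependence, the recommended default
for correlated marker panels), Benjamini–Hochberg, and Bonferroni. The
network keeps edges with adjusted p ≤ α (default 0.05); the full edge table
is always returned, and connected components cover all markers including
isolated nodes. GraphML export carries node degree and per-edge method,
statistic, sign and raw/adjusted p.

## Synthetic cohorts

`synthetic.generate_cohort` draws score panels from a Gaussian copula:
a latent multivariate normal with block-structured correlation provides
rank dependence, and each marker's latent quantile is pushed through the
inverse CDF of its specified marginal, so marginal mixtures are exact while
within-block rank correlation is planted. Batch effects are applied as
y → scale·y + shift per batch; survival times are exponential with a hazard
set by the sample's true mixture group on a designated prognostic marker;
censoring is independent uniform on (0, m) with m solved numerically so the
expected censored fraction hits the target; missingness is completely at
random. Everything is reproducible from a single seed.

The default cohort mirrors a published AQUA breast-cancer panel in shape:
128 samples, 9 continuous markers, two equal batches (the second with
shift +0.75, scale ×1.3 — modest block effects), 30% censoring, 3% missing
cells and a baseline median survival of 60 months over a ~9-year follow-up
scale. Marker M1 is bimodal (30/70 split, 4 SDs apart) with a hazard ratio
of 3 between its groups — the planted prognostic signal; M1–M3 and M4–M6
form correlation blocks (ρ = 0.6); M7–M9 are independent, with mixture
cardinality varied 1–3 across the panel.

What the generator does *not* emulate: heavy-tailed or skewed score noise,
informative (outcome-dependent) censoring and missingness, core-level
replicate correlation, and batch effects that differ per marker. Passing
recovery tests therefore shows the algorithms are implemented correctly
under their own model assumptions, not that real cohorts satisfy those
assumptions.

## Problem sizes used in validation

The recorded operating characteristics use: 50 random pairs (n = 5..9) plus
the complete S lattice at n = 10–12 for Spearman p-values; 200 simulations
of 60 + 60 subjects for log-rank type-I error and power; n = 400 and 100 ×
n = 300 draws for mixture selection; 2 × 100 samples × 8 markers for batch
correction; 50 random censored fixtures against an independent
Kaplan–Meier implementation; 200 replicates × 1000 permutations at n = 200
for the MI null; and 50 default cohorts for end-to-end planted-signal
recovery.

## Known limitations

* Only the parametric empirical-Bayes batch adjustment is provided (no
  nonparametric or reference-batch variant).
* Mixtures are univariate per marker; no multivariate clustering.
* Survival analysis is unadjusted group comparison — no Cox regression,
  multivariable adjustment or competing risks.
* Network inference is marginal association only — no partial correlations
  or sparsity-regularised graphical models, which assume structure that
  small, pathway-focused marker panels need not satisfy.
* Exact reproduction of any particular historical web tool's fits is not
  claimed: restart counts, K caps and variance floors are documented
  choices of this package.
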