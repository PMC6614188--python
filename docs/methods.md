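# Methods

## Model and assumptions

`txanomaly` implements residual analysis for one-class novelty detection on
bulk expression profiles. The working assumption is that healthy tissue
occupies a low-dimensional region of gene-expression space: most of the
training covariance is carried by a few principal components, and the
discarded directions contain only unstructured noise. A detector is a pair
(standardizer, subspace + threshold):

1. **Standardization.** Each gene is z-scored using means and SDs estimated
   on the healthy training cohort (n−1 denominator). Parameters are frozen:
   test samples are expressed in training coordinates, never their own. An
   optional log2(v + pseudocount) transform precedes standardization; the
   default pipeline standardizes FPKM directly and the log step is opt-in
   (recorded in the model, so scoring always replays the exact training
   pipeline).
2. **Subspace.** The training covariance is eigen-decomposed through an
   economy SVD of the standardized genes × samples matrix; with tens of
   thousands of genes and at most a few hundred samples, the p × p
   covariance is never formed. Retained rank k is chosen either as a fixed
   integer or as the smallest k whose cumulative eigenvalue share reaches a
   target fraction (default 0.90).
3. **Score and call.** A sample's anomaly score is the squared prediction
   error Q = ‖z − PPᵀz‖². The call is anomalous iff Q exceeds the control
   limit strictly; a tie is called normal. The per-sample log(Q/Q_α)
   (natural log by default; base recorded in outputs) is the quantity
   plotted against the threshold at zero.

The Q statistic only sees departures *orthogonal* to the retained subspace.
This is by design — a sample that is extreme *within* the healthy modes is,
under the model, an unusual-but-healthy sample — and it is also the
statistic's fundamental blind spot (see limitations).

## Thresholds

The default control limit is the Jackson–Mudholkar closed form, the
canonical limit in multivariate statistical process monitoring. It
approximates the null distribution of Q — a weighted sum of χ² variables
with weights equal to the discarded eigenvalues — using the first three
spectral moments θᵢ = Σ_{j>k} λⱼⁱ:

    h₀  = 1 − 2θ₁θ₃ / (3θ₂²)
    Q_α = θ₁ [ c_α √(2θ₂h₀²)/θ₁ + 1 + θ₂h₀(h₀−1)/θ₁² ]^(1/h₀)

All intermediates (θ₁..θ₃, h₀, c_α) are stored in the model for audit. The
approximation assumes approximately normal standardized data and a
well-populated discarded spectrum; for extreme α or degenerate spectra the
bracket can be non-positive, in which case the code refuses and points to
the alternative: an empirical (1−α) quantile of the training scores (linear
interpolation between order statistics, minimum 20 scores). On Gaussian data
with n ≫ p the two agree closely; the method used is always recorded.

When n ≪ p the training spectrum is rank-deficient and Marchenko–Pastur
spread inflates θ₂ relative to the true residual variance, which makes the
closed-form limit conservative; the empirical quantile is in turn
optimistic, because in-sample residues are shrunk by standardizer and
subspace overfitting. Both biases shrink as the healthy cohort grows — the
mechanism behind the specificity-vs-training-size curve.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| `alpha` | 0.05 | stipulated false-alarm rate; conventional operating point |
| `k` / `variance_fraction` | None / 0.90 | retain the dominant modes; fixed k preferred when the latent dimension is known |
| `log`, `pseudocount` | False, 1.0 | FPKM z-scoring by default; log2(v+1) linearizes multiplicative structure |
| `min_sd` | 1e-8 | drops near-constant genes whose z-scores would blow up |
| `on_missing` | "error" | silently intersecting gene panels changes the model geometry |
| `threshold_method` | Jackson–Mudholkar | closed form, independent of in-sample overfitting |

Eigenvalues below 1e-12 × λ₁ are treated as numerically zero when counting
rank. All evaluation treats cancer/anomaly as the positive class, and
metrics with zero denominators propagate as NA rather than 0 so they cannot
silently corrupt curve averages.

## Synthetic data generator

The generator emulates the latent structure the detector assumes, on the
log2 scale: L = μ + Wz + ε with per-gene intercepts μ ~ N(baseline_log_mean,
baseline_log_sd²), W a p × d matrix with Gram–Schmidt-orthogonalized columns,
z ~ N(0, I_d) per sample and isotropic ε. Expression is 2^L − pseudocount
clipped at zero, so values are non-negative and FPKM-like and the pipeline's
log transform approximately linearizes the structure.

W's columns are scaled to norm √(p/d)·scale_j, so with equal scales s the d
factors jointly contribute variance s² to a typical gene. The defaults
(p = 2000, n = 300, d = 10, s = 3, noise sd σ = 1, baseline mean 6) put
~90% of per-gene variance into the latent block — a strongly structured
tissue — with a median around 64 FPKM and only a small low-expression tail
clipped at zero. Heavier clipping (low baseline or very large factor scales)
visibly erodes the low-rank structure after the log transform; the defaults
keep that distortion marginal.

Anomalies share the healthy (W, μ) and depart in one of two modes:

* **off_subspace** — a displacement δ·u along a fresh random unit vector
  orthogonal to span(W) per sample (anomalies need not resemble each other),
  plus the usual noise. At δ = 0 this is exactly the healthy law. The
  expected Q excess is δ² scaled by the mean inverse squared per-gene
  training sd.
* **factor_inflation** — z is scaled by δ, moving samples far away *within*
  the healthy subspace; the negative control for the residue statistic.

`apply_batch_shift` adds a single shared per-gene log2 offset (sd
`batch_shift_sd`; 0.3 is used as a "mild" shift in the experiments) to every
sample of a cohort, emulating a residual inter-batch bias between training
and test sources; it inflates false alarms without changing the test
samples' biology.

What the generator does **not** emulate: count noise (negative binomial
overdispersion), library-size compositionality, gene–gene correlation beyond
the d factors, heteroscedastic per-gene noise, and intra-batch structure.
Passing tests on this generator therefore validate the machinery and its
calibration under the model's own assumptions — not performance on real
cohorts, where those violations are the dominant difficulty.

## Numerical and design choices

* Ties at the threshold are called normal (strict inequality).
* A score of exactly zero maps to log-ratio −inf; the score table serializes
  it losslessly.
* Training subsets in the size-curve experiment are drawn without
  replacement ("subsets", with an opt-in resampling mode); each
  size × bootstrap cell gets an independently derived sub-seed from the
  master seed, and subset indices are sorted so a full-size subset
  reproduces the full pipeline bit for bit.
* Fitting requires at least one discarded component; exact low-rank training
  data fail at the thresholding step (all discarded eigenvalues zero) with a
  clear error rather than producing a degenerate zero threshold.
* Scoring with `on_missing="intersect"` restricts the standardizer and
  loading rows to the shared genes and re-orthonormalizes the restricted
  loadings; scores then live in a reduced gene space and a warning is
  logged.
* The model file is a single self-describing JSON container (format-version
  tagged) holding the standardizer and detector together, making scoring
  with a mismatched standardizer impossible.

Experiments in the test-suite and the acceptance script use k = d (the
generator's true latent dimension) and the synthetic defaults above; sizes
were chosen so the complete suite runs in minutes on one CPU.

## Known limitations

* **Detection power in high dimensions.** An off-subspace displacement δ
  adds ≈ δ²/σ_g² to the expected Q, but the null Q already fluctuates with
  sd ≈ √(2(p−k))·σ_std². At p = 2000 a displacement of 10 noise-sd units
  shifts Q by only ~1.6 null-sds — no threshold with a controlled
  false-alarm rate can catch most such anomalies, and measured recall at
  α = 0.05 is ~0.23. Power at fixed δ/σ *decreases* with the ambient
  dimension; detecting subtle anomalies requires either stronger
  displacements, feature selection, or test statistics that concentrate the
  signal.
* **The blind spot is only exact for an exactly known subspace.** With a
  finite healthy cohort the fitted subspace deviates from span(W) by a small
  principal angle (~1–5° at the defaults). Within-subspace inflation by δ
  leaks through that angle with variance ∝ sin²θ·δ²·Σλⱼ, which for large δ
  dwarfs the threshold margin: strongly factor-inflated samples are flagged
  with near-certainty despite lying in the modeled subspace. The residue
  statistic's blindness to within-subspace anomalies should therefore be
  understood as an asymptotic property, not a finite-sample guarantee.
* **Threshold calibration degrades as p/n grows** (see Thresholds above);
  with very small cohorts the closed-form limit is conservative and
  specificity is driven by standardizer noise.
* Exact string gene-ID matching only; no normalization or batch correction
  is performed inside the package — inputs are assumed harmonized upstream.
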