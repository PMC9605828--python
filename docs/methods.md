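# Methods

`nirproline` implements a complete desk workflow for quantifying a trace
analyte (serum proline, mg/ml) from near-infrared absorbance spectra:
synthetic data generation with known ground truth, derivative
preprocessing, outlier screening, calibration/validation partitioning, a
from-scratch partial least squares engine, and three wavelength-selection
strategies compared with standard chemometric figures of merit.

## Synthetic spectra

Real serum NIR datasets of this kind are rarely public, so the package
ships a generator whose defaults reproduce the study conditions the
pipeline targets: 207 samples on a 1557-point descending grid from 10000
to 4000 cm⁻¹ (step 6000/1556 ≈ 3.856 cm⁻¹), analyte concentration drawn
from N(0.005234, 0.001866²) mg/ml rejection-truncated to
[0.001917, 0.008198] mg/ml. Because the truncation interval is slightly
asymmetric around the center, the exact mean of the truncated law sits a
few 10⁻⁵ mg/ml below the configured center; tests check the sample mean
against the truncated-normal mean, not the untruncated center.

Each spectrum follows a Beer–Lambert mixture:

    A_i = s_i · (background + c_i · analyte + Σ_j u_ij · interferent_j)
          + a_i + b_i · (ν − ν̄) + ε_i

* **Pure components** are sums of Gaussian bands in wavenumber — the
  standard NIR band approximation, chosen because every downstream claim
  (band location, informative mask, linearity) is then analytically
  checkable. The analyte defaults to the characteristic proline regions
  near 7352, 8620 and 5988 cm⁻¹.
* **Background**: serum is ~90% water, so two broad water-like bands
  (5200 cm⁻¹ combination band, σ = 400; 6900 cm⁻¹ first O–H overtone,
  σ = 300) dominate, with peak absorbance ~2 AU against an analyte
  contribution of ~0.02 AU at the mean concentration.
* **Interferents**: two unnamed co-solutes with per-sample abundance
  u_ij ~ N(1, 0.2) clipped at zero — nothing in the target study
  constrains co-solute statistics, so this is a deliberate, simple choice.
* **Corruptions**: multiplicative scatter s_i = 1 + N(0, 0.01), affine
  baseline drift (offset SD 0.01 AU, slope SD 2·10⁻⁶ AU/cm⁻¹), iid
  additive noise (SD 0.001 AU), and a reference-method (HPLC-like) error
  of 2% of the mean concentration added to the true value to form the
  reference concentration.

Independent RNG streams are spawned per corruption source from one seed,
so disabling one source does not shift the others.

**What the generator does not emulate.** Real serum spectra have
sample-specific *curved* baselines, wavelength-correlated noise,
temperature/solvation shifts of the water bands, and co-solute spectra
correlated with patient physiology. Passing benchmarks on this generator
therefore demonstrates algorithmic correctness and relative behavior
under a bilinear model, not clinical performance.

## Preprocessing

Five treatments: raw, first/second derivative with Savitzky–Golay
smoothing, first/second derivative with the Norris gap-segment filter.
Derivatives are expressed per cm⁻¹ so results are grid-density invariant.

* **Savitzky–Golay** uses `scipy.signal.savgol_filter` with
  `mode="interp"` (boundary windows fit once and their polynomial is
  evaluated at the edge points). Defaults: window 11, polynomial order 3.
  The commonly quoted "5th degree polynomial, 5 point window" setting is
  ill-posed (order must be below the window length), so well-posed
  conventional defaults are used instead; all parameters are exposed.
* **Norris** filter: segment-mean smoothing (width 5), then for the first
  derivative the forward gap difference quotient
  (s[i+g] − s[i])/(ν[i+g] − ν[i]) with gap 5 — chosen so that segment 1 /
  gap 1 reduces exactly to the adjacent difference quotient — and for the
  second derivative the symmetric second difference across two gaps. Edge
  points whose stencil leaves the grid take the nearest valid value, so
  exactness claims (e.g. affine spectra are annihilated by the second
  derivative) hold at interior points, margin = gap + segment//2.

## Screening and partitioning

Spectra are mean-centered and projected onto the leading principal
components (default: smallest dimension retaining 99% variance — the full
1557-dimensional covariance is singular when variables outnumber
samples), and Mahalanobis distances are computed with the scores'
covariance. Dixon's Q test (Rorabacher two-tailed tables; ratio variant
selected by n; applied to the 30 top-ranked distances when the cohort
exceeds the table's range) tests the extreme distance, and Chauvenet's
criterion (flag when n·P(|Z|>z) < ½) tests every distance; a sample is
excluded when either test flags it. Both tests are applied because the
combination rule is genuinely open; OR is the conservative screen.

Partitioning defaults to Kennard–Stone (max–min Euclidean distance,
first pair = global maximum-distance pair, ties to the lower sample
index), 118 calibration / 89 validation at the default cohort size; a
seeded random split is available. Cohorts are summarised as
n/max/min/mean/SD(n−1)/CV and compared with Welch's two-sample t-test
(no equal-variance assumption; the specific test is a package choice).

## PLS engine

Univariate-response NIPALS with mean-centering only (no variance scaling
— conventional for absorbance spectra). For a single response NIPALS is
deterministic and equivalent to SIMPLS. Extraction stops early if the
residual covariance vanishes (exactly collinear data), in which case the
model records the achieved component count. Coefficients are assembled
as B = W(PᵀW)⁻¹q so prediction is an exact affine map.

Latent-variable count is chosen by K-fold cross-validation (default 10
folds, contiguous blocks or a seeded random partition; max 10 LVs):
RMSECV per LV over pooled out-of-fold residuals, global minimum, ties
resolved toward the smaller count (parsimony).

## Wavelength selection

* **SMLR** — classical forward-entry (p < 0.05) / backward-removal
  (p > 0.10) stepwise OLS restricted to a wavenumber window (default
  9503.48–7347.46 cm⁻¹), capped at 15 variables. The forward scan uses
  the partial-correlation form of the coefficient t-test, evaluated for
  all candidates in one vectorized pass; it is algebraically identical to
  refitting OLS per candidate (tested against `statsmodels`).
* **iPLS** — the grid is split into equal-width index intervals (default
  9 → 173 variables each on the 1557-point grid); each interval gets a
  cross-validated PLS model; the interval with the lowest RMSECV wins,
  and the full-spectrum model is fitted alongside for comparison.
* **SA-PLS** — simulated annealing over a binary retention vector V of
  grid length with m retained variables. Each proposal redraws a
  uniformly random mask of size m; the objective is the validation-set
  correlation R_p of an inner 5-LV PLS fit on the retained columns;
  moves are accepted by the Metropolis criterion

      P = 1            if ΔE ≤ 0
      P = exp(−ΔE/T)   if ΔE > 0,     ΔE = R_current − R_proposed

  so improvements (ΔE ≤ 0, boundary included) are always accepted.
  Schedule: geometric cooling T ← 0.95·T every 50 proposals; T₀ is
  auto-calibrated on a 20-proposal warm-up so ~80% of worsening moves
  would initially be accepted (an explicit T₀ can be given; a tiny T₀
  yields greedy search). Initial m is half the grid; on every
  improvement of the global best, m ← max(⌈0.95·m⌉, n_lv), steering the
  search toward sparser masks. Default budget: 2000 iterations. The
  returned model is a refit on the best-ever mask, and the full trace
  (ΔE, temperature, acceptance, m, global best) is recorded; the global
  best is non-decreasing by construction.

  Scoring proposals on the validation set makes the reported SA R_p
  selection-biased (the search maximizes exactly that quantity). This
  mirrors the workflow the package reproduces; users wanting an unbiased
  estimate should hold out a third set.

## Figures of merit

RMSE (RMSEC/RMSEP/RMSECV by set), R = √(max(0, 1 − SSE/SST)) (equal to
|Pearson r| for least-squares-calibrated predictions; both variants are
reported), SEC/SEP = bias-corrected residual SD, offset = mean residual,
RPD = SD(reference)/SEP. These satisfy the identity
RMSE² = SE²·(n−1)/n + offset².

## Pipeline and reproducibility

`run_pipeline` chains generate → preprocess (default second derivative +
Norris) → screen → split → train (SMLR, PLS, iPLS, SA) → report, writing
every intermediate table as CSV plus a manifest (config hash, stage
seeds, output checksums). Every stochastic stage derives its seed as
SHA-256(global seed, stage name) mod 2³¹, making stage results
order-independent; two runs with the same config are numerically
identical.

## Benchmark design and known limitations

Stochastic benchmarks run at the study scale (207 × 1557, 20 seeds) with
medians reported; the SA budget is capped at 800 iterations there, which
the search does not need to exhaust on sparse signals.

* With a single analyte band (σ = 50 cm⁻¹ at 7660 cm⁻¹, ≈5% of variables
  informative) and the pipeline's second-derivative Norris treatment,
  SA-PLS beats full-spectrum PLS in median R_p by a wide margin
  (≈0.90 vs ≈0.84), and iPLS selects the interval containing the
  implanted band in 20/20 seeds.
* **Derivative preprocessing does not beat raw spectra under this
  generator, at any drift strength.** The generator's baseline drift is
  affine per sample — a rank-2 nuisance subspace — and PLS with a
  cross-validated component budget absorbs such a subspace essentially
  perfectly, while derivative filters amplify the iid point noise. The
  well-documented practical advantage of derivative preprocessing comes
  from *curved, sample-specific* baselines and correlated noise that a
  low-rank bilinear model cannot absorb, and those are exactly the real-
  spectra features this generator omits. The corresponding benchmark
  test is kept (and fails) as an honest record of this structural
  limitation rather than being weakened to pass.

Other limitations: no MSC/SNV or wavelet preprocessing (not part of the
compared treatments); no robust covariance screening; single-response
PLS only; no uncertainty quantification on coefficients.
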