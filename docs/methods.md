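# Methods

## The model and the search

A PLS1 calibration relates an absorbance spectrum **x** ∈ ℝᵖ to a scalar
reference content *y* (percent, w/w). `plstraj` fits it with classical
NIPALS on mean-centered data: for each latent factor *a* on the residual
matrices X_a, y_a,

    w_a = X_aᵀ y_a / ‖X_aᵀ y_a‖,  t_a = X_a w_a,
    p_a = X_aᵀ t_a / (t_aᵀ t_a),  q_a = y_aᵀ t_a / (t_aᵀ t_a),
    X_{a+1} = X_a − t_a p_aᵀ,      y_{a+1} = y_a − q_a t_a,

and the regression vector is b = W(PᵀW)⁻¹q. No per-channel variance
scaling is applied: absorbance channels share units, and autoscaling would
inflate noise channels. Scores are pairwise orthogonal by construction and
at full rank the fit coincides with ordinary least squares; both facts are
enforced by tests against independent oracles (pseudoinverse solve,
scikit-learn's PLS implementation is deliberately *not* used in the
implementation, only scipy/numpy linear algebra).

A *path* is a triple (pretreatment chain, latent-factor count A,
variable-selection mode). `run_trajectory` evaluates the full Cartesian
grid — by default 6 pretreatments × A = 1…10 × {full, VIP} = 120 paths —
and selects the best by RPD, with deterministic tie-breaking (smaller
RMSEP, then fewer factors, then menu order, then full variables before
VIP). `stepwise_optimize` implements the conventional comparator: choose
the pretreatment with the best full-variable RMSECV, then the
RMSECV-minimizing A, then keep VIP selection only if it lowers RMSEP. Its
result is one grid member, so the exhaustive search is never worse — an
invariant asserted in the test suite.

Infeasible paths (e.g. VIP retains fewer channels than the requested
factor count allows, or A exceeds n−1 after pretreatment) are recorded as
failed rows with a diagnostic rather than aborting the grid, so trajectory
profiles stay complete. The factor count actually used after feasibility
clipping is reported as `a_effective`, never silently substituted.

## Pretreatments

* **SNV** standardizes each spectrum to mean 0, SD 1 (n−1 denominator).
  It is exactly invariant to per-spectrum affine maps a·x + b (a > 0),
  which is the multiplicative-scatter-plus-offset artifact it targets.
  Constant spectra are rejected with the offending sample named.
* **Savitzky–Golay** coefficients are obtained by solving the local
  polynomial least-squares system directly (Vandermonde pseudoinverse,
  derivative order k scaled by k!); they are tested against both a
  brute-force polynomial-fit oracle and `scipy.signal.savgol_coeffs`.
  Edge channels are filtered with off-center coefficients of the first/
  last full window (equivalent to scipy's `mode="interp"`), keeping the
  output length p and variable indices stable for VIP. Polynomial order
  is fixed at 2 — the conventional chemometrics default, and the lowest
  admitting second derivatives. Derivatives are divided by spacingᵏ using
  the median absolute axis spacing; axes non-uniform beyond 1% relative
  are rejected at load, since a convolution derivative is only meaningful
  on a uniform grid.
* **Labels** (`raw`, `SNV`, `SG(w)`, `1D+SG(w)`, `2D+SG(w)`, composed with
  `+` left-to-right) are the canonical config/report vocabulary. A
  derivative token always fuses with the following SG window into a single
  filter pass; a bare `1D` is deliberately not representable, because an
  unsmoothed difference derivative amplifies noise to no practical benefit.

## Sample selection and validation

Kennard–Stone runs on the raw, uncentered spectra (the split happens once,
before any pretreatment is chosen, so it cannot depend on a per-path
pretreatment) with Euclidean distance; ties break toward the lowest
original index, making splits fully deterministic. The calibration size is
round(n·2/3) half-away-from-zero — 53/27 at n = 80, 48/24 at n = 72.
Cross-validation uses venetian-blind folds (sample i → fold i mod k, k =
10) for the same reason: no randomness anywhere in the analysis path.
Datasets with predefined subsets can bypass Kennard–Stone via an explicit
`--split-file`.

RMSE denominators are plain n for RMSEC, RMSECV and RMSEP (no
degrees-of-freedom correction). R² is 1 − SS_res/SS_tot about the
evaluated set's own mean. RPD is SD(y_validation, n−1)/RMSEP — the
larger-is-better orientation, fixed by checking that benchmark validation
statistics (SD 0.34, RMSEP 0.1256) give ≈ 2.71, in the usual quality
bands. A numerically perfect validation fit (RMSEP = 0, possible only on
idealized synthetic data) is assigned RPD = ∞ rather than an error so
exhaustive grids stay well-defined; the standalone `rpd` operation still
rejects RMSEP ≤ 0.

VIP uses a single selection pass: fit at A factors on all channels, score,
select (threshold 1.0), refit on the selected channels at the feasible
factor count. Iterative re-selection (select → refit → re-score) is not
performed; it rarely changes the retained set and would blur the
interpretation of "VIP at A factors" as one grid axis. If fewer than
max(2, A) channels pass the threshold, the max(2, A) top-scoring channels
are kept so the refit remains feasible — the fallback is recorded via
`n_selected`.

## The synthetic-data generator

`generate` draws from a Beer–Lambert mixing model with layered nuisance
artifacts:

    x_i(λ) = m_i · Σ_k c_ik ε_k(λ) + (a + bλ + cλ²)
             + o_i + s_i(λ − λ̄) + d_i(λ) + noise

with Gaussian absorption bands ε_k, concentrations uniform on each
constituent's range, multiplicative scatter m_i ~ N(1, scatter_sd),
per-sample offset o_i and drift slope s_i, smooth per-sample baseline
wander d_i (low-frequency cosine harmonics with 1/j amplitude decay), and
white noise. The response is the target constituent's concentration, so
ground truth is exact and each artifact can be switched off independently:
with everything off, X is exactly the rank-K mixing model and a K-factor
PLS interpolates it; SNV exactly undoes scatter+offset; a first derivative
exactly annihilates offset and linear drift. Those identities are the
generator's unit tests.

The drift terms deserve a note. A background polynomial shared by all
samples vanishes under mean centering, and scalar per-sample offset/slope
perturbations span only a rank-2 nuisance that PLS absorbs with two extra
factors — neither makes pretreatment choice consequential. Real
instrumental drift is a smooth wavelength-dependent curve that differs per
measurement; the cosine-harmonic wander reproduces that: across samples it
is effectively high-rank, so it cannot be modeled by a few extra latent
factors, while a derivative filter attenuates it strongly relative to the
sharp absorption bands. This is what makes derivative pretreatments win on
the default scenario for the structural reason they win in practice.

**Default scenario** (`corn_like_spec`): 700 channels, 1100–2498 nm at
2 nm; a water-like target (bands at 1190/1450/1940 nm, content
9.38–10.98%) over a dominant carbohydrate matrix (58–70%) and a
protein/oil fraction (6.5–10.5%) with heavily overlapping bands; baseline
0.05 + 2·10⁻⁴·λ; scatter_sd 0.005, offset_sd 0.1 AU, slope_sd 2·10⁻⁴
AU/nm, smooth_drift_sd 0.1 AU (6 harmonics), noise_sd 0.002 AU (~0.2% of
the ~1 AU peak). Drift amplitudes are on the order of the analyte's
spectral signal span (~0.1 AU), i.e. severe but correctable. These
magnitudes were fixed once from pilot runs of the generator design and are
the package's study conditions for all end-to-end tests and the acceptance
script (n = 60, 120-path grid; runs in a few seconds on one CPU).

What the generator does **not** emulate: wavelength-dependent
(MSC-style) scatter, instrument line-shape convolution, detector
nonlinearity, reference-assay error in y, and between-instrument
differences. Passing the end-to-end tests therefore shows the search
machinery and pretreatment algebra behave correctly under the artifact
classes modeled — not that any particular real dataset will reach the same
figures of merit.

## Numerical choices and limitations

* Rank handling: NIPALS stops with an error naming the achievable maximum
  when the response residual or weight norm falls below 10⁻¹² relative;
  grid paths hitting this are flagged, and cross-validation curves shrink
  their factor range if a fold's training set is lower-rank than the full
  set.
* Determinism: two runs on the same input produce byte-identical reports
  (asserted in tests); report metrics are printed to 6 significant digits.
* The trajectory criterion is validation-set RPD. With 120 paths scored on
  one 20–27 sample validation set, the *selected* path's metrics are
  mildly optimistic (winner's curse); for release decisions the chosen
  model should be confirmed on an independent test set, as the
  `predict` subcommand supports.
* PLS2, kernel/O-PLS, MSC/EMSC, wavelet pretreatments, and UVE/CARS/GA
  variable selection are out of scope.
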