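# Methods

This document records the mathematical definitions, numerical choices and
their rationale. Everything here is deterministic given the seeds recorded
in run manifests.

## 1. Model

Coupled Hopf normal-form (Stuart–Landau) oscillators on a weighted
undirected structural connectome `w_ij ≥ 0` (zero diagonal):

```
dz_i/dt = z_i (λ + i ω_i − |z_i|²) + K · tanh( C · Σ_j w_ij x_j ),
x_i = Re z_i
```

- `λ` — shared excitability (bifurcation) parameter. An isolated node has a
  stable fixed point at the origin for `λ < 0` and a stable limit cycle of
  radius `√λ` for `λ > 0`; the Hopf bifurcation is at `λ = 0`.
- `ω_i` — angular natural frequency (rad/s); the synthetic generator draws
  peak frequencies uniformly on 9–11 Hz to emulate regional alpha peaks.
- `K ≥ 0` — global coupling strength, the main fitted parameter.
- `C > 0` — global connectome scaling inside the saturating `tanh`
  (default 20). With `C` large the coupling input saturates and the fit is
  insensitive to its exact value; it is treated as a fixed constant, not
  fitted.
- Optional per-region coupling gain `g_i ≥ 0` multiplies the coupling input
  of region `i`; the synthetic patient model sets `g_i = 1.5` on tumor
  regions (regionally elevated influence of interregional coupling) and 1
  elsewhere.

Coupling acts through the real parts only; `x_i(t)` is the simulated MEG
proxy signal.

### Normalized coupling and the square-root scaling law

Substituting `z → z·√λ` and `t → t/λ` shows that, for `λ` well above the
bifurcation (where the saturated coupling is amplitude-insensitive), the
phase dynamics depends on `(K, λ)` essentially only through

```
k = K / √λ .
```

Consequently the optimal coupling grows as `K_opt = k·√λ` and fits at
different excitabilities are comparable through `k`. `rescaled_equivalent`
maps parameters along these invariance curves; initial conditions are
rescaled by `√(λ'/λ)` so runs start at corresponding points relative to
their limit cycles.

## 2. Numerical integration

Simulations integrate 14.5 s from `t = 0` with the first 1 s discarded as
transient, output sampled at 1250 Hz, using adaptive Dormand–Prince RK45 at
absolute tolerance 1e-6 and relative tolerance 1e-3 (the production
tolerances).

The integrator is a numba-compiled Dormand–Prince implementation with the
standard 4th-order dense-output interpolant and PI-free step control
(error norm with mixed absolute/relative weighting, same tableau as common
scientific ODE suites). A generic Python ODE stack costs ~0.3 s per
14.5 s / 20-region run; the compiled integrator costs ~0.04 s, which is what
makes the grid-search and connectotomy experiments (thousands of runs)
tractable on one CPU. Failure modes (non-finite state, step-size underflow)
raise `IntegrationError` with the failure time.

Two accuracy caveats, both verified against independent solvers and covered
by tests:

- **Limit-cycle radius bias at loose tolerance.** At rtol 1e-3 adaptive RK45
  (ours and scipy's equally) carries a ~1% positive bias in the limit-cycle
  radius at `λ = 9`; at rtol 1e-6 the radius matches `√λ` to ~1e-7. The
  amplitude-law checks therefore integrate at rtol 1e-6 / atol 1e-9 so the
  solver out-resolves the 1% acceptance band. Production runs keep the loose
  tolerance for throughput — PLI depends on phase sign patterns and is
  insensitive to a 1% radial bias.
- **Trajectory-level comparisons need tight tolerances.** Coupled
  oscillators accumulate phase drift, so pointwise agreement with a
  fixed-step RK4 reference (max deviation < 1e-3 over 2 s) is checked at
  rtol 1e-8 / atol 1e-10. This validates the integrator machinery; the
  tolerance is an input, not a property being tested.

Initial conditions are drawn with real and imaginary parts independently
uniform on [−1, 1] — bounded, unbiased and scale-neutral across the
excitability range. Ensembles are seed-paired: every grid cell (and both
connectotomy arms) sees the identical list of initial states.

## 3. Functional connectivity

- **Band-pass**: 4th-order Butterworth 8–12 Hz, applied forward–backward
  (`sosfiltfilt`) so relative phases are not distorted; 0.5 s trimmed from
  both ends afterwards (filter/Hilbert edge artifacts).
- **Phase**: Hilbert analytic-signal angle per channel. An all-zero channel
  raises `DegenerateSignalError`.
- **PLI**: `PLI_ij = |⟨sign(sin(φ_i − φ_j))⟩_t|`, with `sign(0)` contributing
  exactly 0 — identical or anti-phase signals give PLI 0; a constant nonzero
  lag (mod π) gives PLI 1. The implementation wraps the phase difference
  into (−π, π] and takes the sign directly, avoiding trigonometry; a naive
  double-loop `sign(sin(·))` oracle agrees to 1e-12.
- **Epoch averaging**: entrywise mean over a subject's epoch PLIs
  (unthresholded inputs only).
- **Thresholding**: proportional thresholding zeroes exactly
  `floor(P·percent/100)` of the `P = N(N−1)/2` pairs, lowest magnitudes
  first, with a stable (magnitude, row, col) tie order so the count is
  deterministic; median thresholding zeroes pairs strictly below the median
  off-diagonal value. A matrix can be thresholded once; thresholded zeros
  then count as data points in the objective.
- **Spectral peaks**: Welch PSD (2 s Hann segments, 50% overlap), candidate
  peak = argmax above 4 Hz, accepted only if ≥ 2× the mean background
  density over 4–48 Hz excluding ±1 Hz around the candidate. Per-region
  medians across subjects parameterize `ω_i`; regions with no accepted peak
  fall back to the global median (logged).

## 4. Fitting

The goodness of fit of a cell `(K, λ)` is the Pearson correlation between
the off-diagonal upper-triangle entries of simulated and empirical PLI
matrices (≥ 3 retained pairs required; zero variance raises
`UndefinedCorrelationError`). The grid search evaluates each cell on the
shared initial-condition ensemble, giving per-cell distributions of `r` and
per-λ distributions of optimal `K` (argmax over the K grid, ties toward the
smallest K). The default grid is 31 log-spaced K values in [0.1, 30] and
λ ∈ {0, 5, …, 50}.

The normalized coupling is fitted in closed form by least squares through
the origin on `√λ`:

```
k = Σ K̄(λ)·√λ / Σ λ        over λ ≥ λ_min (default 5)
```

Excitabilities below `λ_min` are excluded: near the bifurcation amplitude
dynamics still shape the phases and the square-root law does not hold.

Because simulations never depend on the empirical target, simulated PLIs are
cached and reused across fitting targets — threshold scans and the
patient/control connectotomy arms reuse identical simulations, which is also
what makes those comparisons exactly paired.

## 5. Functional connectotomy

At fixed excitability (`λ = 40` by default) the optimal `K` is computed per
initial condition twice: against the full matrices, and with a set of
(tumor) regions' rows and columns removed *from the Pearson objective only*
— the regions always remain in the simulated dynamics. The patient arm fits
the patient PLI; the control arm reuses the same simulations, mask and
seeds but fits the control-average PLI. The outcome is the paired
per-initial-condition difference `ΔK_patient − ΔK_control`, tested with the
Wilcoxon signed-rank test. A negative mean difference means the masked
regions were pushing the patient fit toward stronger coupling.

A mask must leave at least 3 regions (otherwise the objective is undefined);
an empty mask is a valid identity run with `ΔK = 0` everywhere.

## 6. Statistics

- Wilcoxon rank-sum (Mann–Whitney) for independent samples; the reported
  statistic is the rank sum of the first sample. Exact null by enumeration
  when `min(n, m) ≤ 7` and there are no ties; otherwise normal approximation
  with tie correction.
- Wilcoxon signed-rank for paired differences; zeros are dropped (logged)
  from the test but kept in the reported mean difference. Exact null for
  `n ≤ 15` without tied magnitudes.
- `pool_across_lambda` concatenates per-λ samples with provenance columns
  (`lambda`, `ic`, `value`) for pooled comparisons.
- p-values are two-sided and uncorrected, one test per comparison row.

Both tests are validated against brute-force enumeration of their
permutation nulls (all group labelings; all sign patterns) and a null
calibration check (type-I error at α = 0.05 within [0.03, 0.07] over 2000
repetitions).

## 7. Synthetic data

Real MEG/dMRI cohorts are not distributable, so all inputs are emulated with
known ground truth:

- **Connectome**: Erdős–Rényi topology (default density 0.3) with log-normal
  weights, resampled (bounded retries) until connected; centroids uniform in
  the unit sphere so spatial K-means clustering of tumor regions
  (scikit-learn, 100 restarts, fixed seed) is meaningful.
- **Frequencies**: peak frequencies uniform on 9–11 Hz, stored in Hz,
  consumed as rad/s.
- **"Empirical" PLI**: the model itself simulated at known `(K*, λ*)` for a
  number of epochs from distinct initial conditions, epoch-averaged, plus
  symmetric Gaussian observation noise truncated to [0, 1].
- **Cohort**: reference conditions are `N = 20`, `K* = 8`, `λ* = 40`,
  3 epochs, noise sd 0.02, patients with tumor masks of 2–4 regions at
  coupling gain 1.5. Every draw derives from one master seed through hashed
  child seeds (SHA-256 of the tag tuple), so any subject is regenerable
  bit-identically from its recorded truth.

## 8. Problem sizes and runtime

Reference experiment sizes were chosen to run on a single CPU core:

- scaling check: 2 × 10 simulations (~1 min);
- parameter recovery: 3 λ × 31 K × 10 initial conditions = 930 simulations
  (~2–4 min);
- connectotomy: 31 K × 100 initial conditions = 3100 simulations shared by
  all four objective evaluations (~4–5 min).

## 9. Reproducibility and I/O

Matrix CSVs are written with `float_format="%.17g"` and read with pandas'
round-trip float parsing, so write→read is bit-identical (the default
parser can be off by 1 ulp). JSON sidecars carry provenance (source,
thresholds, sampling rate, truth records). Every pipeline run writes a
manifest with the package version and the fully resolved configuration;
exact stages replay bit-identically from it.

## 10. Limitations

- The generator and the fitted model share the same dynamical family, so
  parameter recovery quantifies identifiability, not biological validity.
- PLI discards zero-lag coupling by construction; effects expressed at zero
  lag are invisible to the objective.
- The square-root scaling is asymptotic in `λ`; fits at `λ < 5` are
  excluded from the `k` regression rather than modeled.
- Observation noise is entrywise Gaussian on PLI values, a simplification of
  sensor-level MEG noise propagated through source reconstruction.
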