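# Methods

## Model and procedure

`dstab` assumes locally linear dynamics: a short window of the N-channel
signal is described by a first-order vector autoregression
`y[n+1] = A y[n] + c + u[n]` with i.i.d. innovations. The propagator's
eigenvalues λ = ρ·e^{iφ} are re-expressed in continuous-time coordinates,
frequency f = |φ|/(2π·dt) in Hz and growth rate τ = log(ρ)/dt in 1/s
(natural logarithm). Conjugate eigenvalue pairs map to the same (f, τ) and
both members are kept, so oscillatory modes count twice at a nonnegative
frequency; this doubles occupancy uniformly and leaves the shape of any
histogram unchanged. Zero eigenvalues (possible in rank-deficient fits)
carry a τ = −∞ sentinel and are excluded from all distributions, with the
exclusion counted.

The pipeline stages are:

1. **Preprocessing** — brick-wall frequency-domain masking: Fourier
   coefficients outside the 5–500 Hz passband or within ±1 Hz of the
   50/100/150 Hz line-noise harmonics are zeroed, everything else passes
   untouched. The mask is a projection, hence exactly zero-phase and
   idempotent; there is no transition band. The synthetic generator
   produces band-limited signals, so synthetic tests may skip this stage.
2. **VAR(1) fitting** — minimum-norm least squares through the SVD-backed
   solver (`rcond = 1e-10` for rank decisions). A δ = 0.5 s window at
   1 kHz holds 500 samples and therefore 499 regression equations (the
   window's transitions, one fewer than its samples). An intercept is fit
   by default as a nuisance parameter — it absorbs any window mean — and is
   never used downstream; disabling it and demeaning per window is an
   equivalent path. Rank-deficient windows return the minimum-norm solution
   with a degenerate-fit warning rather than failing.
3. **DS vectors** — per segment of duration Δ ≥ 0.5 s, ten equally spaced
   δ = 0.5 s fits (overlapping when Δ < 5 s, tiling exactly at Δ = 5 s,
   all coincident in the degenerate Δ = δ case). Pooled modes are binned on
   the 20 × 20 grid τ ∈ [−250, 25] 1/s × f ∈ [4, 256] Hz (log₂-spaced
   frequency edges from 2 to 8 in log₂ Hz). Bins are half-open [lo, hi)
   with the final bin closed; the grid flattens row-major over τ rows with
   frequency varying fastest, giving dimension 400. Vectors carry raw
   counts; an optional per-vector L1 normalization exists but is off by
   default because the classifier standardizes features anyway.
4. **FFT vectors** — per channel, discrete Fourier power at frequencies in
   (0, 100) Hz (DC excluded), floored at 1e−20 of the segment's peak power,
   log-transformed; the vector is the mean across channels of per-channel
   log power. Averaging log power (not log of mean power) keeps the vector
   in the same log-space in which it is defined; the alternative is a
   switch. No taper is applied.
5. **Surrogates** — phase randomization draws uniform phases for
   positive-frequency coefficients with DC/Nyquist fixed, preserving each
   channel's power spectrum exactly. Staggering circularly shifts each
   channel forward by a lag uniform on [0, 0.1·√12 s), i.e. standard
   deviation 100 ms, redrawn each time a segment is selected; global
   staggering draws one lag vector per experiment from width 0.5 s and
   reuses it for every segment. Circular shifting (rather than consuming
   out-of-window data) keeps segment length and per-channel sample
   multisets exact; phase surrogation is applied per segment, matching how
   vectors are constructed.
6. **KS tracking** — the damping-timescale (τ) distribution pooled from 20
   consecutive δ-fits (10 s of data) at each timestamp is compared with an
   initial awake reference pool via the two-sample Kolmogorov–Smirnov
   statistic (statistic only, no p-value). Pool size and step are
   configurable; 20 fits per timestamp is the package default.
7. **Classification** — linear SVM (C = 1) on features standardized with
   parameters estimated from the training half only, so no validation
   information leaks. Per fold, a random half of the training set trains
   and the full validation set is predicted; the error is the percentage
   misclassified, so fold variability reflects training-subsample choice
   only. ROC curves sweep the decision threshold over pooled validation
   scores (all unique scores used); AUC is the trapezoid area; `awake` is
   the positive class; scores at exactly the threshold predict positive.
   A per-fold label-permutation switch provides the chance-level null.

## Synthetic generator

The generator realizes the modeling assumptions exactly: block-diagonal
real matrices of 2 × 2 rotation-scaling blocks (radius e^{τ·dt}, angle
2π·f·dt) per designed mode, optionally conjugated by a random orthogonal
matrix so every channel mixes every mode without moving the spectrum.
Simulation runs the recursion exactly in the eigenbasis via per-mode IIR
filtering (direct time loop as fallback for ill-conditioned
eigendecompositions), with Gaussian innovations of standard deviation 1 and
a 2000-sample burn-in.

Default conditions: N = 16 channels at fs = 1000 Hz; 8 conjugate-pair modes
log-spaced over 6–180 Hz; awake-like regime τ ∈ [−20, 0] 1/s (near
marginal), anesthetized-like regime τ ∈ [−150, −40] 1/s (damped, same
frequency layout); two 60 s intervals separated by a 5 s guard gap. The
interval-trimming safety margin scales as 5% of the interval duration —
the same proportion as a 30 s margin on a ~600 s experimental interval —
so that desk-scale recordings keep usable data. Segment draws default to
500 per interval in the API, reduced (typically 30–40) in tests to keep
the suite fast; classification on the default regimes is insensitive to
this count because the regimes are strongly separable.

The **matched-spectra** variant places the class signal exclusively in
cross-channel structure: both intervals come from one run of the awake-like
generator, and the second interval's channels are desynchronized by fixed
per-channel circular shifts (uniform over [10%, 100%) of the interval).
Circular shifts preserve every per-channel sample multiset and power
spectrum exactly, so spectral features carry no class information, while
the one-step cross-channel predictability that VAR fits exploit is
destroyed — fitted propagators on desynchronized data shrink toward more
damped spectra. This isolates exactly the global, dynamical component of
the classification signal.

What the generator does **not** emulate: 1/f-like broadband spectra,
nonstationary drug kinetics, volume conduction, artifacts, or any
nonlinearity. Passing tests demonstrate that the pipeline recovers and
classifies designed linear dynamics correctly; they do not certify
performance on real recordings.

## Numerical choices

- Grid binning uses `numpy.histogram2d` semantics (last bin closed); an
  independent double-loop histogram serves as the test oracle.
- `lstsq` rcond 1e−10; degenerate fits warn, never raise.
- Simulation refuses designs whose spectral radius would overflow over the
  requested length; design τ is capped at +10 1/s.
- The power floor in FFT vectors is relative (1e−20 × peak power) so
  all-zero channels stay finite.
- Stagger widths convert to whole samples by rounding; a width below one
  sample is an error.
- KS uses the exact two-sample statistic (SciPy); ties are handled by the
  ECDF definition F(x) = P(X ≤ x).

## Problem sizes in tests and the acceptance script

End-to-end checks run 16-channel, 60 s + 60 s recordings with 30–40
segments per interval and 11–50 folds, aggregated over 5–20 seeds. These
sizes were chosen as the smallest at which the designed effects are
comfortably resolved; all scale up through function arguments.

## Known limitations

- Brick-wall filtering rings for signals with sharp temporal edges; the
  intended inputs are long, noise-like recordings where this is
  negligible (segments are long relative to the 5 Hz highpass period).
- The VAR(1) propagator is fit per window independently; no mode tracking
  or smoothing across windows is attempted.
- Near-unit-root (marginal) modes bias ρ̂ slightly downward at finite
  window length; at the 0.5 s windows used here the τ bias is well under
  the grid's 13.75 1/s bin width.
- Cross-subject pooling is supported only through the caller stacking
  feature sets; no domain adaptation is attempted.
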