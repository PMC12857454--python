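# Methods

## Signals and the transition metric

Input is the per-cardiac-cycle mean MAP (mmHg) and MCAv (cm/s) of a repeated
squat–stand (RSS) recording, on the irregular cardiac time grid.  When raw
uniformly sampled waveforms are supplied instead, `beat_processing` averages
them over half-open cardiac-cycle intervals `[onset_i, onset_{i+1})` (each
sample counted exactly once) and stamps each beat at the cycle midpoint; the
midpoint convention is ours — the upstream definition of a "beat time" for a
cycle mean is genuinely open, and the midpoint is symmetric under time
reversal.  Known pressure-device acquisition delays (−250 ms Nexfin,
−1000 ms Finometer) are shipped as named presets and applied as pure time
translations.  Nothing is interpolated or resampled.

For every MAP transition (minimum→maximum: INC; maximum→minimum: DEC) the
engine computes the signed change Δ, interval Δt, rate Δ/Δt for both
signals, the absolute ratio `(ΔMCAv/Δt_MCAv)/(ΔMAP/Δt_MAP)`, and the
relative ratio in which each signal's change is first divided by the
transition's minimum value of that signal (the cycle "baseline").  Ratios
are stored signed — a negative value records MCAv moving against MAP — and
summarised as absolute values.

## Extremum detection

Detection is driven by the protocol half-cycle `h = 1/(2f)`:

- *Detectability*: the series must contain at least one full cycle whose
  smoothed (3-beat moving average) peak-trough amplitude reaches 5 units;
  otherwise a "no oscillation" error.  A beat gap longer than one half-cycle
  is an error naming the gap.
- *Phase*: the earlier of the first cycle's smoothed global minimum /
  maximum anchors the alternation, refined to the raw-beat extremum within
  ±h/2.
- *Walk*: each next extremum is the raw-beat global extremum (first
  occurrence on ties) in the window 0.5–1.5 half-cycles after the previous
  one, guaranteeing alternation and plausible spacing.  The walk also runs
  backward from the anchor, because edge smoothing can make the anchor land
  on the recording's second extremum; a backward candidate is accepted only
  if its excursion from the anchor reaches 60 % of the series' smoothed
  peak-trough amplitude, so a recording that starts mid-slope does not grow
  a spurious boundary extremum.

MCAv extrema are paired to each MAP transition by nearest time of the
same-kind extremum within ±h/2 (MCAv and MAP extrema are not simultaneous —
their interval durations differ systematically).  Transitions lacking a
pairing are kept in the table, excluded, with reason `incomplete`.

## Artifact filters and windows

- *Leading instability* (automated stand-in for the visual discarding of
  atypical first oscillations): leading transitions with |ΔMAP| below 50 %
  of the recording's median |ΔMAP| are excluded until the first passing
  transition; later transitions are never touched by this rule.
- *Outliers*: per direction, over the full recording, the mean and sample
  SD (n−1) of the included |ratio| values are computed once and values
  beyond 3 SD excluded — a single pass, applied independently to the
  absolute and relative ratios, with a transition excluded if either trips.
  The filtered variable (the ratio, per recording) is our reading of an
  under-specified rule; it is the quantity whose artifacts matter
  downstream.  Groups smaller than three are left unfiltered with a warning.
- *Windows*: a transition belongs to the cumulative window `[0, W]` iff its
  terminal MAP extremum time is ≤ W — a transition counts only once
  complete, which reproduces the expected per-direction counts 3/6/9/12/15
  (0.05 Hz) and 6/12/18/24/30 (0.10 Hz) on clean 300 s recordings and makes
  shorter windows exact prefixes of longer ones.  Windows are anchored at
  recording start; excluded transitions are simply absent from the means.

## Reliability battery

For each frequency × direction × metric, each shorter window is compared to
the 300 s reference over participants:

- *Bland–Altman* on per-pair relative differences,
  `100·(short−ref)/pair mean`; bias = mean, limits of agreement = bias ±
  1.96 sample SD.  The pair mean (not the reference) is the denominator so
  the two durations enter symmetrically.
- *CoV* per participant: sample SD of the two values over their mean,
  `|short−ref|/(√2·mean)·100`, summarised by mean, SD and median.
- *ICC*, absolute-agreement two-way model:
  `ICC(A,1) = (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE))` between durations
  (two raters: window and reference) and `ICC(A,k) = (MSR−MSE)/(MSR+(MSC−MSE)/n)`
  within durations, where the raters are the first k transitions of the
  window (k taken as the modal included-transition count, participants with
  fewer dropped).  Confidence intervals use the F-based method of the
  standard two-way framework, with the mean-rating interval obtained by
  Spearman–Brown step-up of the single-rating bounds.  Interpretation bands:
  <0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90) good, ≥0.90 excellent.  A
  table with no variance at all has no defined ICC and is flagged — never
  coerced to 0 or 1.
- *Sample size* for planning a reliability study
  (Walter–Eliasziw–Donner): `n = ⌈1 + 2(z_{α/2}+z_β)²k/((ln C₀)²(k−1))⌉`
  with `θᵢ = ρᵢ/(1−ρᵢ)` and `C₀ = (1+kθ₀)/(1+kθ₁)`.  α is two-sided — the
  only interpretation consistent with the planning value this reproduces
  (ρ₀ = 0.80, ρ₁ = 0.90, α = 0.05, power 0.95, k = 3 → n = 68).

## Group inference

The direction × duration analysis is a two-way fully repeated-measures
ANOVA: each within-subject effect is tested against its own
subject-by-factor interaction.  Greenhouse–Geisser ε is estimated per effect
from the covariance of orthonormal contrast scores and applied automatically
to effects involving a factor with more than two levels (toggleable); ε for
two-level factors is identically 1.  Dunnett-style comparisons of each
duration against 300 s use paired t statistics with a family-wise max-|t|
adjustment evaluated by seeded Monte Carlo over a multivariate-t null
(correlation estimated from the difference scores, common χ² scale, n−1
df; 50 000 draws by default).  This is exact for a single comparison and an
approximation for families, since each contrast keeps its own variance
estimate.  Friedman rank tests handle non-normal covariates; the post hoc
(level vs reference signed-rank with Bonferroni–Holm) is our labelled
interpretation — the classical procedure does not prescribe one.

## Synthetic generator

MAP is a periodic piecewise-linear oscillation: rise over `rise_fraction` of
the cycle (defaults 0.46 at 0.05 Hz, 0.48 at 0.10 Hz, i.e. 9.2/10.8 s and
4.8/5.2 s), amplitude 40 mmHg around a 90 mmHg baseline (62 cm/s for MCAv).
Piecewise-linear rather than sinusoidal forcing keeps every Δ, Δt and rate
analytically exact for oracle tests and matches the square-wave-like
character of postural transitions.  MCAv has one amplitude B per cycle and
its own segment durations; periodicity forces `B·r_MAP/(A·r_MCAv) = g_INC`
and `B·f_MAP/(A·f_MCAv) = g_DEC` to share a single B, so the MCAv durations
are **derived** from the programmed gains:
`B = A·cycle/(r_MAP/g_INC + f_MAP/g_DEC)`.  At the 0.10 Hz defaults
(g = 0.91/1.01) this yields MCAv intervals of 5.06/4.94 s — the directional
gain asymmetry is realised as a timing asymmetry with equal rise and fall
amplitudes, exactly the pattern observed in human cohorts.  Explicit
interval-scale overrides are accepted; the truth record then carries the
realised gains.

Both signals are sampled at jittered cardiac beat times (0.82 ± 0.05 s,
~73 beats/min).  Variability has two levels: small i.i.d. beat noise on the
cycle means (1.0 mmHg MAP, 0.8 cm/s MCAv — cycle averages of 1 kHz signals
carry little instrument noise) and per-cycle physiological amplitude
variability (CV 5 % MAP, plus 4 % independent MCAv), which is where most
real per-transition scatter lives and which, unlike beat noise, cannot bias
extremum timing.  Optional artifact beats (rate 0.005) are half-amplitude
spikes; the first cycle defaults to 40 % amplitude to emulate the unstable
lead-in of a real recording.  Cohorts draw per-participant parameters from
truncated normals around the base configuration with deterministic child
seeds; the directional asymmetry is parameterised separately from the gain
level (SDs 0.05 and 0.15) because it is a within-subject contrast.

`SynthConfig.noiseless(...)` is the oracle mode: zero noise, artifacts and
lead-in, a regular 0.8 s grid, and beats snapped onto the protocol corner
times.  Corner alignment exists because the metric reads extrema off the
discrete beat series: only when a beat samples each true apex can the
pipeline reproduce programmed gains to 1e−9, which the exactness tests
require.

### Measurement attenuation (known, quantified)

With realistic (non-aligned) beats, the detected extremum is the beat
nearest the apex *in value*, and with asymmetric rise/fall slopes that beat
lies on the gentler side slightly more often.  At 0.82 s beats and the
0.10 Hz timing this biases detected maxima late and minima early by
~0.016–0.020 s each, stretching measured INC intervals and shrinking DEC
intervals, which compresses the recovered DEC−INC gain difference by
~0.018 (on a programmed 0.10).  This attenuation is a property of defining
the metric on beat-series extrema — human data sampled at normal heart
rates carry it too — and is therefore documented rather than corrected.

### What the simulations do and do not show

The generator's noise levels are deliberately modest: they reproduce the
qualitative structure of real cohorts (amplitudes and timings within the
observed ±1 SD bands, reliability improving monotonically with duration,
direction effect detectable at n = 30) but *not* the full per-transition
scatter of human recordings, whose within-subject transition CoV is several
times larger — which is precisely why the original reliability study needed
on the order of a hundred participants.  Passing tests therefore certify the
correctness of the machinery and the recoverability of programmed effects
under controlled noise, not field performance on clinical data.

### Problem sizes in the test suite

The behavioural tests use cohorts of 20–30 participants, 100 replicates for
power, 500 for type-I calibration and 50 for reliability monotonicity —
sizes chosen so the full suite completes in a couple of minutes while
keeping Monte-Carlo standard errors well inside the asserted tolerances.

## Degenerate inputs and numerical conventions

Ties in extremum search resolve to the first occurrence.  Zero-SD outlier
groups flag nothing.  Empty windows yield `n_included = 0` with NaN means.
Bland–Altman pairs with zero mean and CoV pairs with non-positive mean are
excluded with warnings; fewer than two pairs is an error.  ICC confidence
bounds are clamped to contain the estimate; perfect-agreement tables return
ICC 1 with a degenerate [1, 1] interval.  The Dunnett correlation matrix is
eigenvalue-clipped to positive semidefinite before Cholesky.  GG ε is
clipped to its theoretical range [1/(levels−1), 1].  All randomness flows
from explicit integer seeds; identical seeds give byte-identical outputs.

## Limitations

No frequency-domain (transfer-function) analysis; no beat-level
autoregulation indices; no modelling of CO₂–flow coupling or respiratory
covariates (the Friedman machinery is exercised on directly generated
covariate tables); the generator's piecewise-linear forcing omits waveform
curvature near the postural transitions; and the within-duration ICC drops
participants whose included-transition count falls below the modal k of the
window.
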