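# cpfr — directional sensitivity of the cerebral pressure–flow relationship

Dynamic cerebral autoregulation buffers rapid arterial pressure changes, but
not symmetrically: middle cerebral artery blood velocity (MCAv) responds less
to acute rises in mean arterial pressure (MAP) than to acute falls.  This
hysteresis-like *directional sensitivity* is quantified on large MAP
oscillations driven by repeated squat–stand maneuvers (RSS) at 0.05 Hz (20 s
cycles) or 0.10 Hz (10 s cycles).  `cpfr` implements the time-adjusted
per-transition ratio metric, the duration-truncation reliability analysis
that asks how much of a 300 s recording is actually needed, and a synthetic
RSS generator with known ground truth so every stage is testable without
human data.

## The metric

Within each squat–stand cycle, MAP rises from a minimum to a maximum (INC)
and falls back (DEC); MCAv follows with its own extrema.  For each
transition the time-adjusted ratio is

```
ΔMCAv_T / ΔMAP_T = (ΔMCAv / Δt_MCAv) / (ΔMAP / Δt_MAP)      [cm/s per mmHg]
```

with Δ the signed change between the transition's extrema of each signal and
Δt the corresponding time interval.  The relative form `%MCAv_T / %MAP_T`
first normalises each signal's change by its cycle minimum ("baseline"), so
cohorts with different resting MAP or MCAv are comparable.  Ratios are
computed per transition on the beat-by-beat (per-cardiac-cycle mean) series
— never interpolated or resampled — filtered (leading unstable oscillations;
single-pass >3 SD outliers per direction), and averaged over cumulative
windows 0–60 s … 0–300 s.  A lower INC than DEC ratio is the directional
sensitivity.

Reliability of each shorter window against the 300 s reference uses
Bland–Altman bias and 95 % limits of agreement on relative differences,
pairwise coefficients of variation, and absolute-agreement two-way ICCs
(between-duration single-rating; within-duration mean-rating), plus a
direction × duration repeated-measures ANOVA with Greenhouse–Geisser
correction, Dunnett-style Monte-Carlo-adjusted comparisons against 300 s,
and Friedman tests for covariates.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
cohorts (20 participants, both frequencies; at 0.10 Hz the programmed gains
are 0.91 INC / 1.01 DEC, at 0.05 Hz both 0.90):

```
python analysis/01_simulate_cohorts.py
python analysis/02_transition_metrics.py
python analysis/03_reliability.py
python analysis/04_group_inference.py
python analysis/05_sample_size.py
```

which prints, among other things:

```
0.1 Hz: 1220 transitions (97% included); 300 s cohort mean ratio INC=1.013 DEC=1.082
0.1 Hz INC, window vs 300 s reference:
    60_vs_300: ICC=0.963 [0.910-0.985]  CoV=2.6%
   120_vs_300: ICC=0.972 [0.931-0.989]  CoV=2.0%
   180_vs_300: ICC=0.982 [0.955-0.993]  CoV=1.4%
   240_vs_300: ICC=0.995 [0.987-0.998]  CoV=0.9%
0.05 Hz ratio_abs: direction effect F(1,19)=1.14, p=0.2999
0.1 Hz ratio_abs: direction effect F(1,19)=26.39, p=5.854e-05
```

Read: the recovered 300 s cohort means sit close to the programmed gains
(the small compression of the INC–DEC contrast is the beat-quantization
attenuation analysed in `docs/methods.md`); reliability improves
monotonically with window length (ICC up, CoV down); and the direction
effect is detected at 0.10 Hz but not at 0.05 Hz, where no asymmetry was
programmed.  `05_sample_size.py` prints the ICC-based planning calculation:
with minimum acceptable reliability 0.80, expected reliability 0.90,
two-sided α = 0.05, power 0.95 and k = 3 repetitions, 68 participants are
required.

The same machinery is scriptable from a shell via the `cpfr` CLI
(`simulate`, `metrics`, `reliability`, `stats`, `all`), with every stage
materialised as tidy CSV.

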