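# Methods

`loombias` re-creates, end to end, the machinery of a two-experiment
psychophysics study of the auditory looming bias: listeners hear a virtual
sound source pass by on a straight path and verbally estimate its speed;
looming (approaching) sources are judged faster than physically identical
receding ones, and close sources faster than distant ones. The package has
three scientific layers — stimulus physics, a synthetic-responder model, and
the factorial analysis — plus an orchestration pipeline. This note records
the models, the defaults and why, and what the tests do and do not show.

## Stimulus geometry and physics

**Geometry.** The listener sits at the origin of a right-handed frame
(x = interaural axis, y = toward the source path, z = up). The source moves
at constant speed (15, 20 or 25 m/s) on a line parallel to the interaural
axis at a 2 m lateral offset and 0.5 m height. "Close" paths span 2–47 m
from the median plane, "distant" paths 15–60 m; both are 45 m long, so
duration = 45/speed (3.0, 2.25, 1.8 s). Looming trials end at the near
bound; receding trials start there; left-side trials mirror x. Listener ear
height is set equal to the source height, making the 2 m offset the true
miss distance — the simplest reading of the plan-view geometry (the study
never states listener height). The offset is measured to the head center;
ears sit at ±8.75 cm along x.

**Rendering.** The source is a square wave (400 Hz fundamental, odd
harmonics at 1/n amplitude), rendered at 44.1 kHz by additive synthesis:
each harmonic's phase is the integral of its instantaneous received
frequency f·n/(1 + v_r/c) (v_r = radial velocity, positive receding,
computed per ear), plus an initial offset −2π·n·f·d(0)/c that encodes the
absolute propagation delay and hence the interaural time difference. This
is exact for a harmonic source and avoids resampling interpolation. The
emission-time correction is omitted: at ≤25 m/s the frequency error is
below 0.5 %, under the 1 % validation tolerance.

Per-sample amplitude combines: the 1/r spreading law (unit gain at 1 m);
atmospheric absorption in the ISO 9613-1 pure-tone form (default air state
20 °C, 50 % RH, 1 atm — the study states none) evaluated at each harmonic's
instantaneous received frequency; a single image source mirrored through the
ground plane with frequency-independent reflectivity 0.95 (no ground
impedance is stated); and a parametric two-ear model — per-ear path lengths
give natural ITD/ILD and the far ear receives a first-order low-pass head
shadow with corner frequency c/(2πa) ≈ 624 Hz for head radius a = 8.75 cm.
Measured-HRTF convolution is deliberately out of scope; none of the
analysis-level conclusions depend on HRTF fidelity.

**Numerical choices.** The odd-harmonic set is fixed per stimulus from the
worst-case approach speed so that the maximum received frequency stays
below 0.95 × Nyquist (no mid-stimulus timbre steps, no aliasing); 10 ms
raised-cosine on/off ramps; one shared normalization constant per battery
(peak 0.98) so inter-stimulus level ratios are preserved; WAV output is
2-channel 16-bit PCM. The validation suite checks, for all 12 conditions:
short-time fundamental within 1 % of the Doppler closed form, short-time
RMS within 2 % of 1/r (absorption/reflection disabled), sample-exact
left/right mirror symmetry, near ear ≥ far ear, and no spectral energy
above the Nyquist margin.

## Synthetic responders

No raw response data exist, so the analysis chain is exercised by a
generative model of verbal speed estimates (m/s scale):

    estimate = max(1, baseline + participant_intercept
                      + direction & distance effects (± half-gaps)
                      + interaction (± quarter-boost)
                      + slope_direction · (true speed − 20) + noise)

* The four Distance × Direction cell locations are calibrated so the
  *truncated* cell means equal the published values exactly (45.9, 35.2,
  32.4, 29.3 m/s for the within-subjects experiment); the inversion solves
  the floor-truncation nonlinearity before the linear map, because a naive
  inversion would bias the low cells by up to ~0.5 m/s.
* Speed sensitivity exists only on looming trials (slope 0.32 for
  experiment 1, 0.28 for experiment 2, per the published speed-marginal
  ordering); the receding slope is 0, encoding the null receding speed
  effect both experiments report.
* Within-participant correlation comes solely from the Gaussian random
  intercept (compound symmetry — exactly the RM-ANOVA's assumption). An
  optional per-speed-level noise term breaks sphericity to exercise the
  Greenhouse–Geisser correction.
* SD split: participant_sd = 19, residual_sd = 6 m/s per trial, putting
  cell SDs near 20 m/s (published range ≈ 19–24). The split assumes a
  stable idiosyncratic verbal scale with comparatively small trial-to-trial
  noise; it is what makes the within-subject effects recoverable at the
  published sample size. A consequence worth knowing: standardized mean
  differences computed from simulated cells (~0.6 for the close contrast)
  run higher than the published 0.47, because d divides by the
  between-participant spread while the within-subject tests do not.
* "Speed of sound" outliers: with probability 3/80 (exp 1) or 11/211
  (exp 2 — the observed replacement rates) a participant answers ~343 m/s
  (Gaussian, SD 30, floored above the 600 mph threshold) on every trial,
  exercising the exclusion filter. Participants report in mph with
  probability 0.7, else km/h (a US-based online sample).
* Truncation at 1 m/s keeps estimates positive; a lognormal
  verbal-estimation model would be the natural swap-in if skewness ever
  mattered, but the analysis consumes means and SDs only.

What passing tests show: the pipeline recovers exactly the effect structure
it injects, at the published sample sizes, with calibrated Type-I error.
What they do not show: anything about real listeners — there is no
psychoacoustic transfer function from waveform to estimate, so responses
are generated from condition labels, never from the audio. That decoupling
is the package's central honest boundary.

## Statistical engine

All statistics are implemented from scratch (scipy supplies only the F, t
and studentized-range distributions):

* **Exclusion**: a participant is dropped iff *all* of their estimates
  exceed 600 mph (mph-equivalent comparison) — the rule both experiments
  applied.
* **Averaging**: the two side-mirrored trials per condition are averaged;
  a missing side keeps the lone value with a warning; a missing whole cell
  is a design error (opt-in for fully-within designs).
* **RM-ANOVA** (any number of crossed within factors): sums of squares via
  Möbius (inclusion–exclusion) marginal-mean effect estimates; every effect
  is tested against its own effect-by-subject interaction. Verified against
  an independent Kronecker-projection oracle on all small instances and
  against statsmodels' AnovaRM.
* **Mixed (split-plot) ANOVA**: between effects against
  subjects-within-groups, within and mixed effects against the
  within-by-subjects-within-groups term. Balanced by design (the study had
  50/cell); mild imbalance (e.g. after exclusions) falls back to unweighted
  cell means with the harmonic mean n, with a warning.
* **Greenhouse–Geisser**: Box's epsilon from the double-centered covariance
  of the within levels; per-effect epsilon uses that effect's orthonormal
  contrast scores (Kronecker-product contrasts), clipped to [1/df, 1].
  Huynh–Feldt is deliberately not offered. GG-corrected p is never smaller
  than the uncorrected p.
* **Partial eta-squared** = SS_effect/(SS_effect + SS_error), which equals
  F·df1/(F·df1 + df2) — the identity used to verify the published tables.
* **Tukey HSD** from level means and the ANOVA error term, p from the
  studentized range distribution (checked against a Monte-Carlo null).
* **Cohen's d** uses the two-group pooled-SD form √((s1²+s2²)/2): it
  reproduces both published values (0.47, 0.15) from the published cell
  statistics exactly, which a paired-difference-SD form would not.
* Degenerate input (all-equal data) reports F = 0, p = 1 rather than 0/0.

## Pipeline, sizes and determinism

`replicate()` chains battery synthesis (optional), response generation,
unit conversion, exclusion, averaging, the experiment's ANOVA, follow-up
one-way speed ANOVAs within each direction, Tukey post hocs, paired t tests
and effect sizes, and emits a provenance record (config hash, seed,
versions) sufficient to reproduce byte-identical outputs. All randomness
flows from one integer seed.

Problem sizes used by the test suite and acceptance script: 12-condition
physical validation on full-length stimuli; parameter recovery over 500
replicates at n = 77; Type-I calibration over 1000 replicates at n = 20
(unadjusted p, since the generator is compound-symmetric and the
uncorrected test is exact there); calibration checks at n = 10 000. A full
Experiment 1 replication (24 stimuli + 77 responders + analysis) takes well
under a minute on one CPU.

## Known limitations

* The published grand-mean speed marginals (~16 m/s in the speed table)
  are inconsistent with the direction/distance marginals (~35 m/s) in the
  source report; the calibration targets the Distance × Direction cell
  means and uses the speed table only for the slope ordering.
* The two-ear model is parametric; no pinna cues, no elevation cues, no
  room reverberation, no near-field range effects.
* The responder model is additive-Gaussian with a floor; it does not model
  reaction times, sex differences, or attention effects.
* Tukey HSD after RM-ANOVA uses the corresponding effect's error MS and df
  with n = number of participants; the original post-hoc error term is not
  stated in the source report.
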