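# Methods

This note documents the models and procedures implemented in `effr`, the
defaults and why they were chosen, what the synthetic-recording generator
does and does not emulate, and the numerical decisions that shape the
results.

## Stimulus and recording model

Stimuli are 500-ms trains of symmetric biphasic pulses (82 µs/phase, 164 µs
total) at pulse rates restricted to integer divisors of the 24 414-samples/s
output rate (`rate = fs / k`), so every period is an exact integer number of
samples.  The default protocol tests 31 rates from 43 to 642 pps with
successive increments of 5–32 pps; `make_rate_list` selects divisors along a
step-clamped geometric progression by dynamic programming (least-squares in
log rate against the continuous clamped-geometric targets, subject to the
increment bounds), anchored so the documented example rate 152.6 pps
(= 24 414/160) is always a member.  Forty trials per rate alternate
anodic/cathodic-leading polarity; epochs span −100 to +650 ms around train
onset.

Each synthetic trial is

`x(t) = Σ_pulses Σ_g w_g(rate) · a_g,ch · k_g(t − t_pulse − L_g) + p · art(t − t_pulse) + noise(t)`

* **Generator kernels** `k_g` are unit-energy difference-of-Gaussians bumps
  (width 1 ms for CN and SOC, 2 ms IC, 4 ms TC/CTX).  The ¼-weighted
  surround keeps the kernel's Fourier transform strictly positive, so the
  response phase at F0 is exactly `−2π F0 L_g` — the ground truth every
  phase test leans on.  Support is truncated at 2.5 widths with the (~10⁻⁶)
  edge value subtracted, so truncation adds no discontinuity.
* **Default ground truth**: CN 1.2 ms (ipsi +9, contra −3.6 µV — the sign
  flip between mastoid channels reflects the local dipole orientation),
  SOC 3.7 ms (+9/+6.6), IC 5.2 ms (+12.6/+25.2, 250-Hz taper), TC/CTX
  13.6 ms (+36/+48, 90-Hz taper).  The latencies are the median fitted
  values a four-generator delay-and-add analysis produces on such data; the
  channel asymmetries (brainstem larger ipsilaterally, midbrain and cortex
  contralaterally) mirror the electrode geometry.
* **Phase-locking taper**: weight 1 below the cut-off, falling linearly (in
  Hz) to 0 one octave above it — the same function the analysis model uses.
* **Per-pulse adaptation**: response amplitude scales as `100 Hz / rate`, so
  each generator's F0 amplitude is approximately rate-independent below its
  taper.  Without it the F0 amplitude of a train of fixed per-pulse
  responses grows ∝ rate (+23 dB/decade over the tested range), a tilt the
  constant-amplitude-sinusoid analysis model cannot represent; with it,
  synthetic amplitude transfer functions have the flat-with-interference
  structure seen in real recordings.
* **AC coupling**: the acquisition chain is high-pass filtered, so evoked
  responses carry no 0-Hz line.  The generator removes each period's mean
  as a uniform level per stimulus period; a constant over exactly one
  period has zero coefficients at every nonzero harmonic, so this emulates
  AC coupling without touching any response phase.
* **Artifact**: a Hann-windowed 2.5-kHz burst over [100, 700] µs — its
  envelope is symmetric about 0.4 ms, so the designed artifact group delay
  equals its energy centroid (0.4 ms) at every frequency — plus a 15 %
  carrier-free envelope component (imperfect charge balance) that gives the
  artifact the low-frequency energy observed at F0 rates, and a small
  (0.5 %) 5-kHz ring decaying to 1.4 ms.  The cathodic-leading artifact is
  −0.85 × the anodic one: electrode polarization makes the two leading
  phases imperfect mirrors, which is why raw polarity averaging alone does
  not null the artifact.  Per-trial gain jitter (±5 %) and timing jitter
  (±1 sample) emulate stimulator/recording asynchrony.
* **Noise**: white + 1/f mixture (50/50 in power), high-passed at 3 Hz,
  0.5 µV RMS, normalized by its expected (not realized) variance so
  trial-to-trial variance keeps its natural spread.  2 % of trials carry a
  3× noise burst ("movement"), which drives the variance screen's
  rejection rate to the few-percent range observed in practice.

What the generator does **not** emulate: volume-conduction head geometry,
radio-frequency or long-voltage-decay artifact components of transcutaneous
implants, onset/offset-specific responses, habituation dynamics beyond an
optional CN latency shift, or inter-subject anatomical variability beyond
amplitude scaling.  Passing tests therefore demonstrate the correctness of
the analysis chain under controlled conditions, not the physiology of any
real recording.

## Artifact reduction

Trials are upsampled ×10 by FFT (trigonometric) interpolation — the
interpolant passes through the original samples, so decimation is an exact
inverse; inputs are zero-padded to an FFT-friendly length first.  Templates
are the mean first-pulse windows [0, 1400] µs per polarity (resampling is
linear, so the mean is taken before the single upsampling); the
cross-polarity mean — carrying the polarity-invariant early neural
response — is subtracted from each polarity's template.  Each pulse's
template is aligned by cross-correlation within ±1 original sample (ties
toward zero lag, boundary hits clamped with a warning), scaled to the
pulse's peak-to-peak amplitude inside the 600-µs main lobe, and subtracted;
the trial is then decimated back before blanking.  Blanking replaces
[onset + 50 µs, onset + 850 µs) with the straight line joining the
boundary samples.  Screening (variance > Q75 + 1.5 IQR within a rate)
precedes polarity-pair averaging.

## Spectral analysis

Amplitudes come from the full-length (450-ms) trial-average spectra,
Hann-ramped over 100 ms and zero-padded to 0.5-Hz bins; phases from the
folded averages (fold interval = the integer number of periods nearest the
lowest rate's 23.3-ms period; ties toward the smaller multiple), Hann-ramped
over 10 ms, evaluated by a direct DFT exactly at F0.  Phases are referenced
to the stimulus by subtracting `2π F0 t_start` (window start re train
onset), so a pure latency reads `−2π F0 L` at every rate and group delays
need no window bookkeeping.  Significance uses the Rayleigh statistic
`z = nR²` on per-pair-trial phases with the finite-n approximation
`p = exp(√(1+4n+4(n²−R²n²)) − (1+2n))`; its measured type-I rate at
p < 0.01 with n = 20 is 0.010.

Known numerical limitation: at the one-or-two-period folds of the lowest
rates the 10-ms ramps cover most of the segment and a harmonic-rich
response leaks some 2F0 energy into the F0 phase (≈0.2 rad worst case at
43 pps, dropping below 0.05 rad once the fold holds ≥3 periods).  This is a
property of the folding recipe itself and is reflected in the tolerances of
the phase tests.

## Delay-and-add model and its fit

The model and grids: CN fixed at 1.2 ms (scalar 1), SOC 2–4 ms in 0.5-ms
steps (scalar 1), IC 4–8 ms in 0.5-ms steps (scalar 2–5), TC/CTX 8–24 ms in
1.25-ms steps (scalar 5–10), with 250/90-Hz one-octave tapers on IC and
TC/CTX — about 1.4 × 10⁴ configurations evaluated exhaustively (cached per
grid and rate axis, since model curves are data-independent).

The fit objective combines the gain-adjusted RMS amplitude error in dB with
the bidirectional mean nearest-feature distance between empirical and model
peaks/dips (capped at 64 pps per feature, weighted at 0.05 dB/pps).  A
feature-count-first (lexicographic) objective was evaluated and rejected:
under per-rate amplitude noise the raw 3-point extremum rule produces
spurious features, and maximizing hit counts first rewards feature-dense
configurations that chase them — latency recovery then fails in most runs
even at 1-dB noise.  The combined objective keeps noiseless on-grid
recovery exact and recovers latencies within one grid step in ≥95 % of runs
at 3-dB iid log-amplitude noise.  Counting unmatched *model* features
symmetrically is what stops feature-dense configurations from free-riding.
Reported hit rates still use the one-to-one greedy matching (peaks↔peaks,
dips↔dips, hit iff within ±32 pps, misses contributing their
nearest-neighbor distance).

Ablations refit with one generator dropped or one taper removed.  On
noiseless four-generator data every ablation raises the RMS error by several
dB; the hit rate never improves but need not fall for every ablation (a
three-generator model can sometimes reproduce the same feature set), so the
tests assert the RMS degradation and non-improvement of hits.

## Group delays and maximum synchrony rates

Cumulative phase lag is the unwrapped negative spectral phase over the
significant rates.  Admissible runs require successive differences
≥ −π/20 rad and gaps ≤ 60 pps (80 pps when fewer than 20 rates are
significant).  The piecewise method partitions the admissible points into 5
segments (4 when ≤ 20 significant rates), each ≥ 3 points, minimizing total
SSE by dynamic programming (verified against exhaustive enumeration); the
slope-equality test on adjacent segments (classic two-slope t-test with
pooled residual variance, identical to the interaction term of the combined
regression) fuses segments at p > 0.05, iterating left-to-right until
stable, within runs only.  The 3-point running method assigns each
3-rate slope to the window's center rate and interpolates to 1 pps;
negative-delay windows are discarded.  Delays < 1 ms are excluded before
maximum synchrony rates are read off (highest rate with τ ≥ the generator's
minimum latency; 1/2/4/8/12 ms for CN/SOC/IC/TC/CTX); the table is
non-increasing from CN to CTX by construction.

A caution quantified during development: with the 800-µs blank covering
37–51 % of the period above 500 pps, the interpolation line contributes a
~0.45-ms-delay component whose weight changes quickly across those rates,
biasing a phase-slope fit restricted to them (a true 2.50-ms delay reads
~1.9 ms there, but 2.50 ms across the full 350–642-pps span).  The blanking
evaluation therefore reports both the >500-pps slope (most sensitive to
residual artifact — it reads the artifact's 0.4-ms latency before
reduction) and the full-span slope (the better latency estimate after
reduction).

## Pipeline, scaling, and experiment design choices

`run_session` executes synthesis → artifact reduction → screening → pairing
→ transfer functions → model fit → group delays → maximum synchrony, per
channel, deterministically for a fixed seed (one master seed; per-trial
substreams).  Inter-session reliability compares each subject's
representative feature set with its other sessions (hit rate over all
comparisons) against a null that redraws each counterpart from a different
subject's sessions with replacement (200 permutations, 95th percentile).

Deliberate experiment-design choices in the tests and acceptance script:

* Full-protocol runs use 31 rates × 40 trials; test-suite sessions scale to
  12–24 trials and/or 12–22 rates, which leaves ≥ 6 polarity pairs for the
  Rayleigh test.
* Noiseless checks disable artifact gain/timing jitter so trials are exactly
  identical (otherwise the variance screen's IQR collapses to ~0 and
  arbitrary trials are flagged — a degenerate case real noise prevents).
* The artifact-delay contrast of the blanking evaluation disables artifact
  timing jitter: after polarity-pair near-cancellation (asymmetry 0.15) the
  residual is small, and jitter-phase differences between the polarity
  means are amplified by ≈1/0.15, swamping the 0.1-ms check.  Jitter
  handling itself is exercised by the template-alignment tests.
* Model-latency recovery through the full pipeline is asserted on the
  ipsilateral channel: the contralateral CN sign flip is a π phase offset
  the all-in-phase model cannot represent (on real data the same model is
  only an approximation there, too).  Maximum-synchrony ordering is
  asserted contralaterally, where the long-latency generators dominate.

## Limitations

* Absolute fitted delays are not neural latencies: only latency differences
  shape the interference pattern, so the fit is ambiguous up to shared
  shifts (and the model cannot represent sign-inverted generators).
* Folded-phase accuracy at one-period folds is limited by ramp leakage (see
  above).
* The blanking interpolation distorts amplitudes and phases increasingly
  with blank fraction; above ~50 % of the period measurements should be
  treated as qualitative.
* The variance screen assumes many trials per rate; below ~8 trials the
  quartile estimates are unstable.
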