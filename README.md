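# effr

Analysis of electrically evoked frequency-following responses (eFFR): scalp
potentials phase-locked to cochlear-implant pulse trains.

Constant-rate biphasic pulse trains (43–642 pulses per second, pps) evoke a
periodic scalp response that aggregates phase-locked activity from several
neural generators — cochlear nucleus (CN), superior olivary complex / lower
brainstem (SOC), inferior colliculus (IC), and thalamocortical/cortical
sources (TC/CTX).  Two obstacles stand between the raw recording and any
statement about neural phase locking: the electric stimulation artifact,
which shares the response's spectrum, and the fact that several generators
superpose at the scalp.  This package implements the full analysis chain for
experimenters working with such recordings:

1. **Artifact reduction** — ×10 band-limited upsampling, per-polarity
   single-pulse template subtraction (templates built from the response-free
   first-pulse windows, aligned per pulse by cross-correlation within ±1
   sample and scaled to each pulse's peak-to-peak amplitude), blanking with
   linear interpolation over [50, 850] µs after each pulse, and averaging of
   anodic/cathodic-leading trial pairs.
2. **Transfer functions** — per-rate response amplitude (full-length
   spectra, 0.5-Hz bins), phase (stimulus-referenced folded spectra), noise
   floors (12 adjacent 2-Hz-spaced bins), and per-rate phase-locking
   significance (Rayleigh test, p < 0.01).
3. **Delay-and-add modeling** of the amplitude transfer function,

   `A(f) = | Σ_g  s_g · w_g(f) · exp(−i 2π f L_g) |`

   with per-generator latency `L_g`, scalar `s_g`, and a linear
   phase-locking taper `w_g(f)` (IC cut-off 250 Hz, TC/CTX 90 Hz, each
   reaching zero one octave above), fitted by exhaustive grid search
   (~1.4 × 10⁴ configurations).
4. **Group delays** from cumulative phase, `τ = Δφ / (2π Δf)`, via optimal
   piecewise linear regression (up to 5 segments, slope-equality fusion)
   and a 3-point running estimator with 1-pps interpolation, leading to each
   generator's **maximum synchrony rate** — the highest pulse rate whose
   group delay still reaches that generator's minimum latency
   (CN 1, SOC 2, IC 4, TC 8, CTX 12 ms).

Because such recordings are not publicly distributable, the package includes
a first-class synthetic-recording generator (`effr.synthetic_data`) that
emulates multi-generator responses with known latencies, per-pulse
stimulation artifact with polarity alternation, gain/timing jitter, and
white + 1/f noise — so every stage is testable against ground truth.

## Worked example

```python
from effr.pipeline import run_session

report = run_session({"synthesis": {"stimulus": {"n_trials_per_rate": 16}}}, seed=1)
for ch in report.channels:
    s = ch.summary()
    print(ch.channel, s["n_significant"], s["model_fit"]["latencies_ms"],
          s["max_sync_pps"]["average"])
```

This synthesizes a two-channel session (31 rates, 16 trials each) from the
default four-generator ground truth (latencies 1.2 / 3.7 / 5.2 / 13.6 ms),
runs the full chain, and prints per channel:

```
channel 0 (ipsi)
  significant rates: 31 / 31
  rejection fraction: 0.034
  fitted latencies (ms): [1.2, 3.5, 5.5, 14.25]
  hit rate: 0.86  rms dB: 3.62
  piecewise group delays (ms): [12.2, 0.7, 3.8, 3.0]
  max sync (avg, pps): {'CN': 531, 'SOC': 531, 'IC': 217, 'TC': 142, 'CTX': 132}
channel 1 (contra)
  significant rates: 31 / 31
  fitted latencies (ms): [1.2, 3.5, 7.0, 15.5]
  hit rate: 0.82  rms dB: 4.02
  piecewise group delays (ms): [12.6, 2.8, 6.7, 2.7]
  max sync (avg, pps): {'CN': 634, 'SOC': 634, 'IC': 557, 'TC': 289, 'CTX': 108}
```

Reading this: every pulse rate is significantly phase-locked; ~3% of trials
fail the variance screen; the grid fit recovers the generating latencies to
within one grid step on the ipsilateral channel (3.5 / 5.5 / 14.25 ms vs the
true 3.7 / 5.2 / 13.6); group delays transition from thalamocortical (~12 ms)
at low rates to brainstem-like (~3 ms) at high rates; and the maximum
synchrony rates fall off along the pathway (contralateral channel:
CTX 108 < TC 289 < IC 557 < SOC 634 pps).

A thin CLI wraps the same functions:

```
effr synth --seed 1 --out rec.h5
effr run --seed 1 --out outdir/
effr artifact-reduce --in rec.h5 --out clean.h5 --blank-len 800 [--sweep 200:1600:200]
effr group-delay --in outdir/transfer_function_ch1.csv --method piecewise --out delays.csv
```

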