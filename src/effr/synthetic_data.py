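"""Synthetic eFFR recording generator.

Emulates two-channel scalp recordings evoked by constant-amplitude biphasic
pulse trains delivered through a cochlear implant: per-pulse responses of
latency-separated neural generators (cochlear nucleus through cortex) with
rate-dependent phase-locking tapers, a per-pulse stimulation artifact whose
sign flips with the leading-phase polarity, additive white + 1/f noise, and
small per-trial artifact gain/timing jitter.  Every downstream analysis stage
can therefore be tested against a known ground truth without any recorded
data.

Conventions
-----------
* channel 0 is ipsilateral and channel 1 contralateral to the implant;
  the cochlear-nucleus response flips sign between the channels.
* anodic-leading polarity is +1, cathodic-leading is -1; the artifact of a
  cathodic-leading pulse is the negative of the anodic one (up to jitter).
* amplitudes are in microvolts; times in the trial epoch are in seconds
  relative to the pulse-train onset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .delay_add_model import taper_weight

__all__ = [
    "StimulusSpec",
    "NeuralGenerator",
    "GeneratorGroundTruth",
    "ArtifactSpec",
    "NoiseSpec",
    "RecordingSet",
    "make_rate_list",
    "default_rate_list",
    "synth_pulse_train",
    "artifact_waveform",
    "neural_kernel",
    "synth_session",
    "default_ground_truth",
]

ANODIC = 1
CATHODIC = -1


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Pulse-train stimulation protocol.

    Pulse rates must have an integer number of samples per period
    (rate = sample_rate / k); trials alternate anodic/cathodic-leading
    polarity, 40 per rate by default (20 per polarity).
    """

    sample_rate: float = 24414.0
    pulse_rates: tuple[float, ...] = ()
    phase_dur_us: float = 82.0
    train_dur_ms: float = 500.0
    epoch_ms: tuple[float, float] = (-100.0, 650.0)
    inter_train_ms: float = 1200.0
    jitter_frac: float = 0.05
    n_trials_per_rate: int = 40

    def __post_init__(self):
        if self.n_trials_per_rate % 2:
            raise ValueError("n_trials_per_rate must be even (paired polarities)")
        if self.train_dur_ms > self.epoch_ms[1]:
            raise ValueError("train duration must fit in the post-onset epoch")
        for r in self.pulse_rates:
            self.samples_per_period(r)

    def samples_per_period(self, rate: float) -> int:
        spp = self.sample_rate / rate
        if abs(spp - round(spp)) > 1e-6:
            raise ValueError(f"rate {rate} pps has non-integer samples per period")
        return int(round(spp))

    @property
    def train_samples(self) -> int:
        return int(round(self.train_dur_ms * 1e-3 * self.sample_rate))

    @property
    def epoch_samples(self) -> int:
        return self.onset_index + int(round(self.epoch_ms[1] * 1e-3 * self.sample_rate))

    @property
    def onset_index(self) -> int:
        """Sample index of the pulse-train onset within the epoch."""
        return int(round(-self.epoch_ms[0] * 1e-3 * self.sample_rate))

    def time(self) -> np.ndarray:
        """Epoch time base in seconds, 0 at train onset."""
        return (np.arange(self.epoch_samples) - self.onset_index) / self.sample_rate

    def pulse_onsets(self, rate: float) -> np.ndarray:
        """Pulse-onset sample indices relative to the train onset."""
        spp = self.samples_per_period(rate)
        return np.arange(0, self.train_samples, spp, dtype=int)


def _clamped_geometric_targets(r0, r_end, m, min_step, max_step):
    """Continuous target rates: m-step geometric progression with per-step
    clamps, the ratio bisected so the last target lands on ``r_end``."""

    def seq(q):
        t = [r0]
        for _ in range(m):
            t.append(min(max(t[-1] * q, t[-1] + min_step), t[-1] + max_step))
        return t

    lo, hi = 1.0, 2.0 * (r0 + max_step) / r0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if seq(mid)[-1] < r_end:
            lo = mid
        else:
            hi = mid
    out = seq(0.5 * (lo + hi))
    out[-1] = r_end
    return out


def _build_piece(fs, k_start, k_end, m, min_step, max_step):
    """Divisor sequence of ``m`` increments from ``k_start`` to ``k_end``.

    Dynamic program over divisors: every increment must stay within
    [min_step, max_step] pps, and among feasible sequences the one closest
    (least squares in log rate) to the continuous clamped-geometric targets
    is selected.
    """
    targets = _clamped_geometric_targets(fs / k_start, fs / k_end, m, min_step, max_step)
    ks = np.arange(k_end, k_start + 1)  # ascending k = descending rate
    rates = fs / ks
    log_r = np.log(rates)
    inf = np.inf
    cost = np.full((m + 1, ks.size), inf)
    prev = np.full((m + 1, ks.size), -1, dtype=int)
    cost[0, ks.size - 1] = 0.0  # start at k_start
    for i in range(1, m + 1):
        dev = (log_r - math.log(targets[i])) ** 2
        for j in range(ks.size):
            # predecessors: rate in [rates[j]-max_step, rates[j]-min_step]
            lo_r, hi_r = rates[j] - max_step, rates[j] - min_step
            if hi_r <= 0:
                continue
            lo_k = int(math.ceil(fs / hi_r))
            hi_k = int(math.floor(fs / lo_r)) if lo_r > 0 else k_start
            lo_j = lo_k - k_end
            hi_j = hi_k - k_end
            lo_j = max(lo_j, j + 1)  # predecessor must have larger k
            hi_j = min(hi_j, ks.size - 1)
            if lo_j > hi_j:
                continue
            window = cost[i - 1, lo_j : hi_j + 1]
            b = int(np.argmin(window))
            if window[b] < inf:
                cost[i, j] = window[b] + dev[j]
                prev[i, j] = lo_j + b
    if not np.isfinite(cost[m, 0]):
        raise ValueError("infeasible spacing for requested n_rates")
    path = [0]
    for i in range(m, 0, -1):
        path.append(int(prev[i, path[-1]]))
    path.reverse()
    return [int(ks[j]) for j in path]


def make_rate_list(
    sample_rate: float,
    r_min: float,
    r_max: float,
    n_rates: int,
    min_step: float = 5.0,
    max_step: float = 32.0,
    anchors: tuple[float, ...] = (),
) -> list[float]:
    """Pulse rates with integer samples per period spanning [r_min, r_max].

    Rates are of the form ``sample_rate / k`` (k integer), selected greedily
    along a step-clamped geometric progression so successive increments stay
    within [min_step, max_step] pps where achievable.  ``anchors`` are rates
    that must appear in the list (snapped to the divisor grid); the range is
    split at each anchor and the requested count allocated across the pieces
    in proportion to their log spans.
    """
    if n_rates < 1:
        raise ValueError("n_rates must be >= 1")
    k_hi = max(1, round(sample_rate / r_min))
    k_lo = max(1, round(sample_rate / r_max))
    r0, r_end = sample_rate / k_hi, sample_rate / k_lo
    if n_rates == 1:
        return [r0]
    if k_lo >= k_hi:
        raise ValueError("r_min and r_max resolve to the same divisor rate")
    span = r_end - r0
    if not (min_step * (n_rates - 1) <= span <= max_step * (n_rates - 1)):
        raise ValueError(
            f"cannot span {span:.1f} pps with {n_rates - 1} increments of "
            f"{min_step}-{max_step} pps"
        )

    # split the range at anchors (each snapped to its divisor rate)
    edges = [r0]
    for a in sorted(anchors):
        ka = round(sample_rate / a)
        ra = sample_rate / ka
        if r0 < ra < r_end:
            edges.append(ra)
    edges.append(r_end)

    # allocate interval counts per piece proportional to log span
    n_int = n_rates - 1
    logs = np.diff(np.log(edges))
    spans = np.diff(edges)
    alloc = np.maximum(1, np.floor(n_int * logs / logs.sum()).astype(int))
    while alloc.sum() < n_int:
        alloc[np.argmax(logs / alloc)] += 1
    while alloc.sum() > n_int:
        i = int(np.argmin(logs / alloc))
        if alloc[i] <= 1:
            raise ValueError("too many anchors for the requested n_rates")
        alloc[i] -= 1
    # minimum achievable interval count per piece (greedy max-climb over the
    # divisor grid; snapping makes exactly max_step increments unattainable),
    # stealing intervals from roomy pieces where needed
    def _min_intervals(ra, rb):
        k = round(sample_rate / ra)
        k_stop = round(sample_rate / rb)
        m = 0
        while k > k_stop:
            k = max(k_stop, min(k - 1, int(math.ceil(sample_rate / (sample_rate / k + max_step)))))
            m += 1
        return m

    need = np.array([_min_intervals(a, b) for a, b in zip(edges, edges[1:])])
    for _ in range(n_int):
        short = np.nonzero(alloc < need)[0]
        if short.size == 0:
            break
        donors = np.nonzero((alloc > need) & (spans / (alloc - 1).clip(min=1) >= min_step))[0]
        donors = [d for d in donors if d not in short and alloc[d] > 1]
        if not donors:
            raise ValueError("infeasible spacing for requested n_rates/anchors")
        j = max(donors, key=lambda d: alloc[d] - need[d])
        alloc[j] -= 1
        alloc[short[0]] += 1

    ks: list[int] = [k_hi]
    for (a, b), m in zip(zip(edges, edges[1:]), alloc):
        piece = _build_piece(sample_rate, ks[-1], round(sample_rate / b), int(m), min_step, max_step)
        ks.extend(piece[1:])
    return [sample_rate / k for k in ks]


def default_rate_list(sample_rate: float = 24414.0) -> list[float]:
    """The default 31-rate protocol, 43-642 pps, anchored so the published
    example rate 152.6 pps (= sample_rate/160) is included."""
    return make_rate_list(sample_rate, 43.0, 642.0, 31, anchors=(152.5875,))


def synth_pulse_train(rate: float, spec: StimulusSpec, polarity: int = ANODIC):
    """Biphasic pulse train at exact integer-sample periods.

    Returns ``(waveform, onsets)`` where onsets are pulse-onset sample indices
    re the train onset.  Cathodic-leading trains are the negative of
    anodic-leading ones.
    """
    if polarity not in (ANODIC, CATHODIC):
        raise ValueError("polarity must be +1 (anodic) or -1 (cathodic)")
    onsets = spec.pulse_onsets(rate)
    n = spec.train_samples
    phase_samples = max(1, int(round(spec.phase_dur_us * 1e-6 * spec.sample_rate)))
    pulse = np.concatenate([np.ones(phase_samples), -np.ones(phase_samples)]) * polarity
    wave = np.zeros(n)
    for o in onsets:
        seg = pulse[: n - o]
        wave[o : o + seg.size] += seg
    return wave, onsets


# ---------------------------------------------------------------------------
# ground truth: neural generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuralGenerator:
    """A latency-separated neural source contributing to the scalp response.

    ``amp_uv`` is the signed per-channel amplitude (ipsi, contra); the
    cochlear nucleus flips sign between channels.  The per-pulse response is a
    unit-energy difference-of-Gaussians bump of the given width, so its
    spectrum is real and positive and the response phase at F0 is exactly
    ``-2 pi F0 latency``.  Phase locking tapers linearly to zero from
    ``taper_cutoff_hz`` to one octave (``taper_octaves``) above it.

    Per-pulse adaptation scales the response by ``adapt_ref_hz / rate`` so
    that each generator's F0 amplitude is approximately rate-independent
    below its taper (as more pulses arrive per second, each evokes a
    proportionally smaller response); ``adapt_ref_hz=None`` disables it.
    """

    name: str
    latency_ms: float
    amp_uv: tuple[float, float]
    width_ms: float = 1.0
    taper_cutoff_hz: float | None = None
    taper_octaves: float = 1.0
    adapt_ref_hz: float | None = 100.0
    habituation_ms: float = 0.0  # extra latency at the highest rate (0 = off)

    def weight(self, rate_pps) -> np.ndarray:
        w = taper_weight(rate_pps, self.taper_cutoff_hz, self.taper_octaves)
        if self.adapt_ref_hz is not None:
            w = w * (self.adapt_ref_hz / np.asarray(rate_pps, dtype=float))
        return w

    def latency_at(self, rate_pps: float, r_min=43.0, r_max=642.0) -> float:
        if self.habituation_ms == 0.0:
            return self.latency_ms
        frac = np.clip((rate_pps - r_min) / (r_max - r_min), 0.0, 1.0)
        return self.latency_ms + self.habituation_ms * float(frac)


@dataclass(frozen=True)
class GeneratorGroundTruth:
    generators: tuple[NeuralGenerator, ...]

    def __post_init__(self):
        lat = [g.latency_ms for g in self.generators]
        if any(b <= a for a, b in zip(lat, lat[1:])):
            raise ValueError("generator latencies must be strictly increasing")
        if any(not np.isfinite(g.amp_uv).all() for g in self.generators):
            raise ValueError("generator amplitudes must be finite")


def default_ground_truth() -> GeneratorGroundTruth:
    """Four generators at the median fitted latencies of the delay-and-add
    model (1.2, 3.7, 5.2, 13.6 ms): cochlear nucleus (sign-flipped across
    channels, largest ipsilaterally), brainstem/SOC, inferior colliculus
    (largest contralaterally, 250-Hz taper), and a merged thalamic/cortical
    source (90-Hz taper)."""
    return GeneratorGroundTruth(
        (
            NeuralGenerator("CN", 1.2, (9.0, -3.6), width_ms=1.0),
            NeuralGenerator("SOC", 3.7, (9.0, 6.6), width_ms=1.0),
            NeuralGenerator("IC", 5.2, (12.6, 25.2), width_ms=2.0, taper_cutoff_hz=250.0),
            NeuralGenerator("TC/CTX", 13.6, (36.0, 48.0), width_ms=4.0, taper_cutoff_hz=90.0),
        )
    )


def neural_kernel(t_s, width_ms: float) -> np.ndarray:
    """Unit-energy difference-of-Gaussians bump, centered at t = 0.

    k(t) = g(t; sigma) - g(t; 2 sigma)/4 with sigma = width/4 (ms); the 1/4
    surround keeps the Fourier transform strictly positive, so a generator's
    response phase at F0 equals -2 pi F0 L exactly.  Support is truncated at
    |t| <= 2.5 * width, with the (already ~1e-6) edge value subtracted so the
    truncation introduces no discontinuity.
    """
    t = np.asarray(t_s, dtype=float)
    s = width_ms * 1e-3 / 4.0
    half = 2.5 * width_ms * 1e-3

    def g(x):
        return np.exp(-(x**2) / (2 * s**2)) - 0.25 * np.exp(-(x**2) / (8 * s**2))

    k = g(t) - g(np.array(half))
    k[np.abs(t) > half] = 0.0
    energy = np.sqrt(np.sum(k**2))
    return k / energy if energy > 0 else k


# ---------------------------------------------------------------------------
# artifact
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """Per-pulse stimulation artifact model.

    The main lobe is a Hann-windowed cosine burst over
    [main_start_us, main_start_us + main_dur_us] -- its envelope is symmetric
    about the window center, so the designed group delay equals the energy
    centroid (0.4 ms by default) -- followed by low-amplitude amplifier-style
    ringing decaying out to ``support_us``.  The anodic-leading artifact is
    the negative of the cathodic-leading one up to per-trial gain jitter;
    per-trial timing jitter never exceeds +/- 1 sample at the acquisition
    rate, which keeps the jittered main lobe inside the default 50-850-us
    blanking window.
    """

    peak_uv: float = 200.0
    main_start_us: float = 100.0
    main_dur_us: float = 600.0
    carrier_hz: float = 2500.0
    #: carrier-free fraction of the main envelope (imperfect charge balance);
    #: gives the artifact the low-frequency energy seen at F0 rates while
    #: keeping its phase linear (the envelope stays symmetric about 0.4 ms)
    lowfreq_frac: float = 0.15
    ring_hz: float = 5000.0
    ring_frac: float = 0.005
    ring_tau_us: float = 120.0
    support_us: float = 1400.0
    gain_jitter: float = 0.05
    time_jitter_samples: int = 1
    #: cathodic-leading artifact is -(1 - polarity_asymmetry) times the anodic
    #: one: electrode polarization makes the two leading phases imperfect
    #: mirrors, so polarity averaging alone cannot null the artifact
    polarity_asymmetry: float = 0.15
    channel_gain: tuple[float, float] = (1.0, 0.7)

    def __post_init__(self):
        if self.support_us > 1400.0 + 1e-9:
            raise ValueError("artifact support must lie within [0, 1400] us")

    def energy_centroid_ms(self, sample_rate: float = 24414.0) -> float:
        """Designed artifact latency: temporal centroid of squared amplitude."""
        t = np.arange(0.0, self.support_us * 1e-6, 1.0 / (10 * sample_rate))
        a = artifact_waveform(t, self)
        e = a**2
        return float(np.sum(t * e) / np.sum(e) * 1e3)


def artifact_waveform(t_s, spec: ArtifactSpec) -> np.ndarray:
    """Anodic-leading artifact sampled at times ``t_s`` (s re pulse onset)."""
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    a = spec.main_start_us * 1e-6
    T = spec.main_dur_us * 1e-6
    t0 = a + T / 2.0
    main = (t >= a) & (t < a + T)
    env = np.sin(np.pi * (t[main] - a) / T) ** 2
    out[main] = spec.peak_uv * env * (
        np.cos(2 * np.pi * spec.carrier_hz * (t[main] - t0)) + spec.lowfreq_frac
    )
    ring = (t >= a + T) & (t < spec.support_us * 1e-6)
    tr = t[ring] - (a + T)
    out[ring] = (
        spec.peak_uv
        * spec.ring_frac
        * np.cos(2 * np.pi * spec.ring_hz * tr)
        * np.exp(-tr / (spec.ring_tau_us * 1e-6))
    )
    return out


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """White + 1/f trial noise, high-pass filtered at 3 Hz (the acquisition
    high-pass), with occasional high-variance 'movement' trials (noise burst
    applied to a whole trial) to exercise outlier screening at a realistic
    few-percent rejection rate."""

    rms_uv: float = 0.5
    pink_frac: float = 0.5
    highpass_hz: float = 3.0
    burst_prob: float = 0.02
    burst_gain: float = 3.0


def _colored_noise(rng: np.random.Generator, n: int, spec: NoiseSpec, fs: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if spec.pink_frac <= 0:
        return spec.rms_uv * white
    z = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    shape[f < spec.highpass_hz] = 0.0
    pink = np.fft.irfft(z * shape, n)
    # normalize by the expected (not realized) std, so trial-to-trial variance
    # keeps its natural spread (Parseval: E[sum x^2] = s0^2 + 2 sum s_mid^2 + s_ny^2)
    e_var = (shape[0] ** 2 + 2 * np.sum(shape[1:-1] ** 2) + shape[-1] ** 2) / n
    pink /= math.sqrt(e_var)
    mix = math.sqrt(1 - spec.pink_frac) * white + math.sqrt(spec.pink_frac) * pink
    return spec.rms_uv * mix


# ---------------------------------------------------------------------------
# recording container + session synthesis
# ---------------------------------------------------------------------------

@dataclass
class RecordingSet:
    """Per-trial, per-channel epoched scalp waveforms with labels.

    ``waveforms`` has shape (n_trials, n_samples, 2); ``rate`` and
    ``polarity`` label each trial; ``time`` is seconds re the train onset.
    ``onsets`` maps each rate to pulse-onset sample indices within the epoch.
    """

    waveforms: np.ndarray
    rate: np.ndarray
    polarity: np.ndarray
    time: np.ndarray
    sample_rate: float
    onsets: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.waveforms.ndim != 3 or self.waveforms.shape[2] != 2:
            raise ValueError("waveforms must be (trials, samples, 2 channels)")
        if len(self.rate) != len(self.waveforms) or len(self.polarity) != len(self.waveforms):
            raise ValueError("labels must cover every trial")

    @property
    def rates(self) -> np.ndarray:
        return np.unique(self.rate)

    @property
    def onset_index(self) -> int:
        return int(np.searchsorted(self.time, -0.5 / self.sample_rate))

    def select(self, rate: float, polarity: int | None = None) -> np.ndarray:
        m = np.isclose(self.rate, rate)
        if polarity is not None:
            m &= self.polarity == polarity
        return self.waveforms[m]


def synth_session(
    spec: StimulusSpec,
    truth: GeneratorGroundTruth | None = None,
    artifact: ArtifactSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> RecordingSet:
    """Simulate a full recording session.

    Each trial is the superposition of (a) per-pulse generator responses
    weighted by the rate-dependent phase-locking taper, (b) the polarity-
    signed per-pulse artifact with optional gain/timing jitter, and (c)
    additive noise.  Reproducible for a fixed seed; the ground truth travels
    in ``provenance``.
    """
    truth = truth if truth is not None else default_ground_truth()
    artifact = artifact if artifact is not None else ArtifactSpec()
    noise = noise if noise is not None else NoiseSpec()
    if not spec.pulse_rates:
        raise ValueError("StimulusSpec.pulse_rates is empty")
    for g in truth.generators:
        if not np.isfinite([g.latency_ms, g.width_ms]).all():
            raise ValueError("NaN/inf generator parameters")

    fs = spec.sample_rate
    n_samp = spec.epoch_samples
    i_on = spec.onset_index
    n_trials = spec.n_trials_per_rate
    rates = list(spec.pulse_rates)
    total = len(rates) * n_trials

    waveforms = np.zeros((total, n_samp, 2))
    rate_lab = np.zeros(total)
    pol_lab = np.zeros(total, dtype=int)
    onsets_map = {}

    # artifact sampled on the +/-1-sample shifted grids once
    t_art = np.arange(0.0, artifact.support_us * 1e-6, 1.0 / fs)
    art_base = {
        dt: artifact_waveform(t_art - dt / fs, artifact)
        for dt in range(-artifact.time_jitter_samples, artifact.time_jitter_samples + 1)
    }

    master = np.random.default_rng(seed)
    trial_seeds = master.integers(0, 2**31 - 1, size=(len(rates), n_trials))

    idx = 0
    for ri, rate in enumerate(rates):
        onsets = spec.pulse_onsets(rate) + i_on
        onsets_map[rate] = onsets

        # per-pulse neural response for this rate (same for every trial)
        spp = spec.samples_per_period(rate)
        neural = np.zeros((n_samp, 2))
        for g in truth.generators:
            w = float(g.weight(rate))
            if w == 0.0:
                continue
            lat = g.latency_at(rate)
            half = int(round(2.5 * g.width_ms * 1e-3 * fs)) + 2
            j = np.arange(-half + int(round(lat * 1e-3 * fs)), half + int(round(lat * 1e-3 * fs)) + 1)
            kern = neural_kernel(j / fs - lat * 1e-3, g.width_ms)
            for ch in (0, 1):
                amp = w * g.amp_uv[ch]
                if amp == 0.0:
                    continue
                for o in onsets:
                    lo, hi = o + j[0], o + j[-1] + 1
                    klo = max(0, -lo)
                    khi = kern.size - max(0, hi - n_samp)
                    neural[max(0, lo) : min(hi, n_samp), ch] += amp * kern[klo:khi]
                # AC coupling of the acquisition chain: remove the per-period
                # mean as a uniform level across each stimulus period.  A
                # constant over exactly one period has zero coefficients at
                # every nonzero harmonic, so response phases are untouched.
                level = amp * kern.sum() / spp
                for o in onsets:
                    hi = min(o + spp, n_samp)
                    neural[o:hi, ch] -= level

        for ti in range(n_trials):
            pol = ANODIC if ti % 2 == 0 else CATHODIC
            rng = np.random.default_rng(int(trial_seeds[ri, ti]))
            w = neural.copy()
            if artifact.peak_uv != 0.0:
                gain = 1.0 + (artifact.gain_jitter * rng.uniform(-1, 1) if artifact.gain_jitter else 0.0)
                if pol == CATHODIC:
                    gain *= 1.0 - artifact.polarity_asymmetry
                dt = int(rng.integers(-artifact.time_jitter_samples, artifact.time_jitter_samples + 1)) if artifact.time_jitter_samples else 0
                a = art_base[dt]
                for o in onsets:
                    hi = min(o + a.size, n_samp)
                    for ch in (0, 1):
                        w[o:hi, ch] += pol * gain * artifact.channel_gain[ch] * a[: hi - o]
            if noise.rms_uv > 0:
                burst = noise.burst_gain if rng.uniform() < noise.burst_prob else 1.0
                for ch in (0, 1):
                    w[:, ch] += burst * _colored_noise(rng, n_samp, noise, fs)
            waveforms[idx] = w
            rate_lab[idx] = rate
            pol_lab[idx] = pol
            idx += 1

    prov = {
        "seed": seed,
        "generators": [
            {
                "name": g.name,
                "latency_ms": g.latency_ms,
                "amp_uv": list(g.amp_uv),
                "width_ms": g.width_ms,
                "taper_cutoff_hz": g.taper_cutoff_hz,
                "taper_octaves": g.taper_octaves,
            }
            for g in truth.generators
        ],
        "artifact_centroid_ms": artifact.energy_centroid_ms(fs) if artifact.peak_uv else None,
        "noise_rms_uv": noise.rms_uv,
    }
    return RecordingSet(
        waveforms=waveforms,
        rate=rate_lab,
        polarity=pol_lab,
        time=spec.time(),
        sample_rate=fs,
        onsets=onsets_map,
        provenance=prov,
    )
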