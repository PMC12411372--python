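"""Per-pulse stimulation-artifact removal.

Three cooperating steps, applied per channel:

1. **Template subtraction** — trials are upsampled x10 (band-limited FFT
   interpolation), a per-polarity single-pulse template is built from the
   first-pulse windows [0, 1400 us] of all trains (the cross-polarity mean,
   which carries the polarity-invariant neural response, is subtracted from
   each polarity's template), and each pulse's template is aligned by
   cross-correlation within +/- 1 original sample, scaled to the pulse's
   peak-to-peak amplitude, and subtracted.
2. **Blanking + linear interpolation** — a fixed window starting 50 us after
   each pulse onset (800 us long by default) is replaced by the straight line
   joining the boundary samples.
3. **Polarity-pair averaging** — anodic/cathodic-leading trial pairs are
   averaged, cancelling any residual sign-flipping artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft, signal

from .synthetic_data import ANODIC, CATHODIC, RecordingSet

__all__ = [
    "UPSAMPLE",
    "ArtifactTemplate",
    "BlankingConfig",
    "upsample_x10",
    "downsample_x10",
    "build_templates",
    "subtract_templates",
    "blank_interpolate",
    "polarity_pair_average",
    "reduce_recording",
    "blanking_sweep",
]

UPSAMPLE = 10
TEMPLATE_US = 1400.0
P2P_WINDOW_US = 600.0  # artifact main lobe, used for peak-to-peak scaling
BLANK_START_US = 50.0


def upsample_x10(waveform: np.ndarray, sample_rate: float) -> np.ndarray:
    """Band-limited x10 upsampling (FFT interpolation).

    The trigonometric interpolant passes through the original samples, so
    taking every 10th output sample recovers the input to machine precision.
    """
    x = np.asarray(waveform, dtype=float)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty waveform")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform must be finite")
    # zero-pad to an FFT-friendly length; the interpolant still passes through
    # every input sample, so decimation remains an exact inverse
    m = fft.next_fast_len(n)
    if m != n:
        pad = np.zeros(x.shape[:-1] + (m,))
        pad[..., :n] = x
        x = pad
    return signal.resample(x, m * UPSAMPLE, axis=-1)[..., : n * UPSAMPLE]


def downsample_x10(waveform: np.ndarray) -> np.ndarray:
    """Inverse of :func:`upsample_x10` (decimation by sample picking)."""
    return np.asarray(waveform)[..., ::UPSAMPLE]


@dataclass
class ArtifactTemplate:
    """Per-polarity single-pulse artifact templates at the x10 rate."""

    anodic: np.ndarray
    cathodic: np.ndarray
    sample_rate_x10: float

    def __post_init__(self):
        if self.anodic.shape != self.cathodic.shape:
            raise ValueError("polarity templates must have equal length")

    def for_polarity(self, polarity: int) -> np.ndarray:
        return self.anodic if polarity == ANODIC else self.cathodic

    @property
    def n_samples(self) -> int:
        return self.anodic.size


def _template_len(sample_rate: float) -> int:
    return int(round(TEMPLATE_US * 1e-6 * sample_rate * UPSAMPLE))


def build_templates(recordings: RecordingSet, channel: int = 0) -> ArtifactTemplate:
    """Build per-polarity single-pulse artifact templates.

    The template is the mean over all trains (all rates) of the upsampled
    first-pulse window [0, 1400 us]; the average of the anodic and cathodic
    templates — primarily the polarity-invariant early neural response — is
    subtracted from each, leaving equal-magnitude, opposite-sign artifact
    models.
    """
    fs = recordings.sample_rate
    i_on = recordings.onset_index
    n_tpl = _template_len(fs)
    need = i_on + int(np.ceil(TEMPLATE_US * 1e-6 * fs)) + 1
    if recordings.waveforms.shape[1] < need:
        raise ValueError("epoch does not cover 1400 us after the train onset")
    means = {}
    for pol in (ANODIC, CATHODIC):
        mask = recordings.polarity == pol
        if not mask.any():
            raise ValueError("missing polarity; templates need both leading phases")
        # resampling is linear, so the mean may be taken first (one FFT per polarity)
        mean = recordings.waveforms[mask, :, channel].mean(axis=0)
        up = upsample_x10(mean, fs)
        means[pol] = up[i_on * UPSAMPLE : i_on * UPSAMPLE + n_tpl]
    common = 0.5 * (means[ANODIC] + means[CATHODIC])
    return ArtifactTemplate(
        anodic=means[ANODIC] - common,
        cathodic=means[CATHODIC] - common,
        sample_rate_x10=fs * UPSAMPLE,
    )


def _subtract_upsampled(
    x10: np.ndarray,
    template: np.ndarray,
    onsets_x10: np.ndarray,
    max_shift: int = UPSAMPLE,
) -> np.ndarray:
    """Template subtraction on an upsampled trial (in place on a copy).

    For each pulse, the template is shifted by the cross-correlation peak lag
    within ``+/- max_shift`` upsampled samples (ties toward zero shift),
    scaled to the pulse's peak-to-peak amplitude within the artifact main
    lobe [0, 600 us], and subtracted.
    """
    y = np.array(x10, dtype=float)
    n_tpl = template.size
    n_p2p = int(round(n_tpl * P2P_WINDOW_US / TEMPLATE_US))
    tpl_p2p = template[:n_p2p].max() - template[:n_p2p].min()
    if tpl_p2p == 0:
        return y
    clamped = False
    for o in onsets_x10:
        lo_lag = max(-max_shift, -o)
        hi_lag = min(max_shift, y.size - n_tpl - o)
        if hi_lag < lo_lag:
            continue  # template does not fit at this onset
        lag_axis = np.arange(lo_lag, hi_lag + 1)
        seg_ext = y[o + lo_lag : o + hi_lag + n_tpl]
        xc = np.correlate(seg_ext, template, mode="valid")
        # ties (to numerical precision) break toward zero shift
        order = np.argsort(np.abs(lag_axis), kind="stable")
        tol = 1e-12 * max(1.0, abs(xc.max()))
        best_lag = int(lag_axis[order][xc[order] >= xc.max() - tol][0])
        if abs(best_lag) == max_shift:
            clamped = True
        seg = y[o + best_lag : o + best_lag + n_tpl]
        if seg.size < n_tpl:
            continue
        scale = (seg[:n_p2p].max() - seg[:n_p2p].min()) / tpl_p2p
        seg -= scale * template
    if clamped:
        warnings.warn("alignment hit the +/-1-sample search bound; shift clamped")
    return y


def subtract_templates(
    trial: np.ndarray,
    template: np.ndarray | ArtifactTemplate,
    pulse_onsets: np.ndarray,
    sample_rate: float,
    polarity: int = ANODIC,
) -> np.ndarray:
    """Subtract aligned, scaled single-pulse templates from one trial.

    ``trial`` and ``pulse_onsets`` are at the original rate; processing runs
    at the x10 rate and the result is decimated back.
    """
    tpl = template.for_polarity(polarity) if isinstance(template, ArtifactTemplate) else template
    x10 = upsample_x10(trial, sample_rate)
    onsets_x10 = np.asarray(pulse_onsets, dtype=int) * UPSAMPLE
    return downsample_x10(_subtract_upsampled(x10, tpl, onsets_x10))


@dataclass(frozen=True)
class BlankingConfig:
    """Post-pulse blanking window (us re pulse onset)."""

    blank_start_us: float = BLANK_START_US
    blank_len_us: float = 800.0
    sweep_lengths_us: tuple[float, ...] = tuple(np.arange(200.0, 1600.0 + 1e-9, 200.0))

    def fraction_of_period(self, rate_pps: float) -> float:
        return self.blank_len_us * 1e-6 * rate_pps


def blank_interpolate(
    trial: np.ndarray,
    pulse_onsets: np.ndarray,
    sample_rate: float,
    cfg: BlankingConfig | None = None,
    rate_pps: float | None = None,
) -> np.ndarray:
    """Blank [onset+50 us, onset+50+len us) and linearly interpolate across.

    Samples inside the window are replaced by the straight line joining the
    samples just outside the window; everything else is untouched.
    """
    cfg = cfg or BlankingConfig()
    if rate_pps is not None and cfg.fraction_of_period(rate_pps) >= 1.0:
        raise ValueError("blanking window covers the whole inter-pulse interval")
    y = np.array(trial, dtype=float)
    n = y.shape[-1]
    d0 = int(round(cfg.blank_start_us * 1e-6 * sample_rate))
    d1 = int(round((cfg.blank_start_us + cfg.blank_len_us) * 1e-6 * sample_rate))
    for o in np.asarray(pulse_onsets, dtype=int):
        i0, i1 = o + d0, o + d1
        if i0 <= 0 or i1 >= n or i1 <= i0:
            continue
        y[..., i0:i1] = np.interp(
            np.arange(i0, i1), [i0 - 1, i1], [y[..., i0 - 1], y[..., i1]]
        )
    return y


def polarity_pair_average(
    trials: np.ndarray, polarities: np.ndarray
) -> np.ndarray:
    """Average anodic/cathodic-leading trial pairs (i-th with i-th).

    Residual sign-flipping artifact cancels; polarity-invariant neural
    content is preserved.  Unpaired excess trials are dropped with a warning.
    """
    trials = np.asarray(trials)
    polarities = np.asarray(polarities)
    an = trials[polarities == ANODIC]
    ca = trials[polarities == CATHODIC]
    n = min(len(an), len(ca))
    if n == 0:
        raise ValueError("need at least one trial of each polarity")
    if len(an) != len(ca):
        warnings.warn("unpaired trial counts; dropping the excess trials")
    return 0.5 * (an[:n] + ca[:n])


def reduce_recording(
    recordings: RecordingSet,
    cfg: BlankingConfig | None = None,
    channel: int = 0,
    template_subtraction: bool = True,
    blanking: bool = True,
    pair_average: bool = True,
) -> dict[float, np.ndarray]:
    """Run the full artifact-reduction chain for one channel.

    Returns a map rate -> (n_trials_or_pairs, n_samples) cleaned epochs.
    Stages can be disabled individually for evaluation sweeps.
    """
    cfg = cfg or BlankingConfig()
    fs = recordings.sample_rate
    template = build_templates(recordings, channel) if template_subtraction else None
    out: dict[float, np.ndarray] = {}
    for rate in recordings.rates:
        mask = np.isclose(recordings.rate, rate)
        trials = recordings.waveforms[mask, :, channel]
        pols = recordings.polarity[mask]
        onsets = recordings.onsets[float(rate)]
        # a blank covering the whole inter-pulse interval cannot be applied;
        # the sweep marks such (length, rate) cells invalid downstream
        blank_here = blanking and cfg.fraction_of_period(float(rate)) < 1.0
        cleaned = []
        for w, pol in zip(trials, pols):
            if template is not None:
                w = subtract_templates(w, template, onsets, fs, pol)
            if blank_here:
                w = blank_interpolate(w, onsets, fs, cfg, rate_pps=float(rate))
            cleaned.append(w)
        cleaned = np.asarray(cleaned)
        out[float(rate)] = (
            polarity_pair_average(cleaned, pols) if pair_average else cleaned
        )
    return out


def blanking_sweep(
    recordings: RecordingSet,
    lengths_us: tuple[float, ...] | None = None,
    channel: int = 0,
    high_rate_pps: float = 500.0,
) -> pd.DataFrame:
    """Evaluate artifact-reduction conditions across blanking lengths.

    For each condition (no reduction, template subtraction only, and template
    subtraction plus each blanking length) the F0 + harmonics 2-4 summed
    amplitude and noise per rate are computed, together with the group delay
    over the pulse rates above ``high_rate_pps`` — the rates most sensitive
    to residual artifact.  Blanking lengths exceeding a rate's inter-pulse
    interval flag that cell invalid.
    """
    from .group_delay import high_rate_group_delay  # deferred: avoids cycle
    from .spectral_analysis import build_transfer_function
    from .waveform_processing import analysis_window

    if lengths_us is None:
        lengths_us = BlankingConfig().sweep_lengths_us
    if not np.any(recordings.rates > high_rate_pps):
        warnings.warn("no rates above the high-rate cut; group delay undefined")

    fs = recordings.sample_rate
    i_on = recordings.onset_index
    conditions: list[tuple[str, float | None, bool]] = [("no_reduction", None, False)]
    conditions.append(("ts_only", None, True))
    conditions += [(f"blank_{int(L)}us", L, True) for L in lengths_us]

    rows = []
    for name, L, ts in conditions:
        cfg = BlankingConfig(blank_len_us=L) if L is not None else None
        cleaned = reduce_recording(
            recordings, cfg, channel,
            template_subtraction=ts, blanking=L is not None,
        )
        windowed = {}
        t_start = None
        for rate, pairs in cleaned.items():
            win, start = analysis_window(pairs, fs, i_on)
            windowed[rate] = win
            t_start = start / fs
        tf = build_transfer_function(windowed, fs, t_start, channel, with_harmonics=True)
        delay_ms = high_rate_group_delay(tf, min_rate_pps=high_rate_pps)
        # single-line fit across the whole tested span: less sensitive to the
        # rate-local phase distortion of wide blanking fractions
        full_delay_ms = high_rate_group_delay(tf, min_rate_pps=0.0)
        for i, rate in enumerate(tf.rates_pps):
            invalid = L is not None and L * 1e-6 * rate >= 1.0
            rows.append(
                {
                    "condition": name,
                    "blank_len_us": L if L is not None else np.nan,
                    "rate_pps": rate,
                    "sum_amp_uv": tf.amplitude_uv[i]
                    + (tf.harmonic_amplitude_uv[i].sum() if tf.harmonic_amplitude_uv is not None else 0.0),
                    "sum_noise_uv": tf.noise_uv[i]
                    + (tf.harmonic_noise_uv[i].sum() if tf.harmonic_noise_uv is not None else 0.0),
                    "significant": bool(tf.significant[i]),
                    "high_rate_group_delay_ms": delay_ms,
                    "full_span_group_delay_ms": full_delay_ms,
                    "invalid": invalid,
                }
            )
    return pd.DataFrame(rows)
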