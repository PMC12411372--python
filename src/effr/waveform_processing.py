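"""Trial screening, analysis windowing, folding, and the display filter.

Analysis proceeds on the 450-ms portion of each epoch starting 50 ms after
the pulse-train onset (onset-specific responses excluded).  For phase
analysis, waveforms are additionally folded: averaged over segments whose
length is the integer number of stimulus periods nearest to the period of
the lowest pulse rate (~23.3 ms for 43 pps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FoldedWaveform",
    "ScreeningReport",
    "reject_outlier_trials",
    "analysis_window",
    "fold_waveform",
    "bandpass_display",
    "DEFAULT_FOLD_BASE_MS",
]

#: folding base interval: the period of the lowest pulse rate (43 pps)
DEFAULT_FOLD_BASE_MS = 1000.0 / 43.0


@dataclass
class ScreeningReport:
    n_total: int
    n_rejected: int
    kept_index: np.ndarray

    @property
    def rejection_fraction(self) -> float:
        return self.n_rejected / self.n_total


def reject_outlier_trials(trials: np.ndarray):
    """Variance-based outlier screening within one pulse rate.

    A trial is kept iff its time-domain variance does not exceed the 75th
    percentile of variances across trials by more than 1.5 times the
    interquartile range.

    Parameters
    ----------
    trials : (n_trials, n_samples) array

    Returns
    -------
    kept : (n_kept, n_samples) array
    report : ScreeningReport
    """
    trials = np.asarray(trials)
    if trials.ndim != 2 or trials.shape[0] < 4:
        raise ValueError("need >= 4 trials for variance screening")
    v = trials.var(axis=1)
    q25, q75 = np.percentile(v, [25, 75])
    keep = v <= q75 + 1.5 * (q75 - q25)
    if not keep.any():
        raise ValueError("all trials rejected by variance screening")
    report = ScreeningReport(
        n_total=trials.shape[0],
        n_rejected=int((~keep).sum()),
        kept_index=np.nonzero(keep)[0],
    )
    return trials[keep], report


def analysis_window(
    trial: np.ndarray,
    sample_rate: float,
    onset_index: int,
    start_ms: float = 50.0,
    dur_ms: float = 450.0,
):
    """Extract the post-onset analysis portion of an epoched trial.

    Returns ``(windowed, start_index_re_onset)`` where the second value is the
    sample offset of the window start relative to the train onset (needed to
    reference spectral phases to the stimulus).
    """
    i0 = onset_index + int(round(start_ms * 1e-3 * sample_rate))
    i1 = onset_index + int(round((start_ms + dur_ms) * 1e-3 * sample_rate))
    trial = np.asarray(trial)
    if trial.shape[-1] < i1:
        raise ValueError("epoch too short for the requested analysis window")
    return trial[..., i0:i1], i0 - onset_index


@dataclass
class FoldedWaveform:
    rate_pps: float
    fold_interval_ms: float
    n_periods: int
    n_segments: int
    waveform: np.ndarray  # mean segment
    sample_rate: float


def fold_waveform(
    waveform: np.ndarray,
    rate_pps: float,
    sample_rate: float,
    base_interval_ms: float = DEFAULT_FOLD_BASE_MS,
) -> FoldedWaveform:
    """Average an analysis-windowed waveform over stimulus-periodic segments.

    The fold interval is ``k`` periods of the pulse rate with
    ``k = round(base_interval / period)`` (ties toward smaller k, k >= 1);
    the mean is taken over all complete segments.
    """
    waveform = np.asarray(waveform)
    spp = sample_rate / rate_pps
    if abs(spp - round(spp)) > 1e-6:
        raise ValueError("rate must have an integer number of samples per period")
    spp = int(round(spp))
    base_samples = base_interval_ms * 1e-3 * sample_rate
    ratio = base_samples / spp
    k = int(np.floor(ratio + 0.5))
    if abs((ratio % 1.0) - 0.5) < 1e-12:  # tie: prefer the smaller multiple
        k = int(np.floor(ratio))
    k = max(k, 1)
    interval = k * spp
    n_seg = waveform.shape[-1] // interval
    if n_seg < 1:
        raise ValueError("waveform shorter than one fold interval")
    segs = waveform[..., : n_seg * interval].reshape(*waveform.shape[:-1], n_seg, interval)
    return FoldedWaveform(
        rate_pps=rate_pps,
        fold_interval_ms=interval / sample_rate * 1e3,
        n_periods=k,
        n_segments=n_seg,
        waveform=segs.mean(axis=-2),
        sample_rate=sample_rate,
    )


def bandpass_display(
    waveform: np.ndarray,
    sample_rate: float,
    band_hz: tuple[float, float] = (40.0, 1500.0),
) -> np.ndarray:
    """Zero-phase 40-1500-Hz band-pass for waveform display and peak reading.

    A first-order Butterworth prototype is doubled by the band-pass design and
    doubled again by forward-backward filtering, for an effective fourth-order
    response.  Spectral analysis never uses this filter.
    """
    lo, hi = band_hz
    nyq = sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError("invalid band edges")
    sos = signal.butter(1, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(waveform, dtype=float), axis=-1)
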