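"""End-to-end session orchestration and inter-session reliability.

A session runs, in order: recording synthesis (or loading), per-channel
artifact reduction, trial screening, polarity-pair averaging, transfer-
function assembly, peak/dip detection, delay-and-add model fitting, phase
unwrapping with both group-delay estimators, and the per-generator maximum
synchrony rates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .artifact_reduction import BlankingConfig, blank_interpolate, build_templates, polarity_pair_average, subtract_templates
from .delay_add_model import FeatureSet, GridSpec, ModelFit, fit_model, match_features
from .group_delay import (
    DelaySeries,
    GroupDelayConfig,
    PhaseSegment,
    max_sync_rates,
    phase_curve_from_tf,
    piecewise_fit,
    running_group_delay_3pt,
    segments_to_series,
)
from .spectral_analysis import TransferFunction, build_transfer_function, detect_peaks_dips
from .synthetic_data import (
    ArtifactSpec,
    GeneratorGroundTruth,
    NeuralGenerator,
    NoiseSpec,
    RecordingSet,
    StimulusSpec,
    default_ground_truth,
    default_rate_list,
    synth_session,
)
from .waveform_processing import analysis_window, reject_outlier_trials

log = logging.getLogger("effr")

__all__ = [
    "ChannelResult",
    "SessionReport",
    "session_spec_from_config",
    "prepare_trials",
    "analyze_channel",
    "run_session",
    "intersession_reliability",
]


@dataclass
class ChannelResult:
    channel: int
    tf: TransferFunction
    features: FeatureSet
    fit: ModelFit | None
    segments: list[PhaseSegment]
    piecewise: DelaySeries
    running: DelaySeries
    max_sync: dict  # method -> generator -> pps
    n_rejected: int
    n_trials: int

    def summary(self) -> dict:
        avg = {
            g: float(np.nanmean([self.max_sync["piecewise"][g], self.max_sync["running3"][g]]))
            if not (math.isnan(self.max_sync["piecewise"][g]) and math.isnan(self.max_sync["running3"][g]))
            else math.nan
            for g in self.max_sync["piecewise"]
        }
        return {
            "channel": self.channel,
            "n_significant": int(self.tf.significant.sum()),
            "n_rates": len(self.tf.rates_pps),
            "rejection_fraction": self.n_rejected / self.n_trials,
            "features": {"peaks": list(self.features.peaks), "dips": list(self.features.dips)},
            "model_fit": self.fit.summary() if self.fit else None,
            "group_delays_ms": [s.tau_ms for s in self.segments],
            "segment_rate_ranges": [s.rate_range_pps for s in self.segments],
            "max_sync_pps": {**self.max_sync, "average": avg},
        }


@dataclass
class SessionReport:
    channels: list[ChannelResult]
    config: dict
    seed: int | None
    version: str = __version__

    def summary(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "channels": [c.summary() for c in self.channels],
        }


def session_spec_from_config(config: dict):
    """Build (StimulusSpec, GeneratorGroundTruth, ArtifactSpec, NoiseSpec)
    from a config dict's ``synthesis`` block.  Every stimulus and generator
    constant is surfaced here; omitted blocks fall back to defaults."""
    syn = config.get("synthesis", {})
    stim_kwargs = dict(syn.get("stimulus", {}))
    if "pulse_rates" not in stim_kwargs:
        stim_kwargs["pulse_rates"] = tuple(default_rate_list(stim_kwargs.get("sample_rate", 24414.0)))
    else:
        stim_kwargs["pulse_rates"] = tuple(stim_kwargs["pulse_rates"])
    spec = StimulusSpec(**stim_kwargs)
    if "generators" in syn:
        truth = GeneratorGroundTruth(
            tuple(NeuralGenerator(**{**g, "amp_uv": tuple(g["amp_uv"])}) for g in syn["generators"])
        )
    else:
        truth = default_ground_truth()
    artifact = ArtifactSpec(**syn.get("artifact", {}))
    noise = NoiseSpec(**syn.get("noise", {}))
    return spec, truth, artifact, noise


def prepare_trials(
    rec: RecordingSet,
    channel: int,
    blanking: BlankingConfig | None = None,
    template_subtraction: bool = True,
    do_blanking: bool = True,
):
    """Artifact reduction + screening + pairing + windowing for one channel.

    Returns ``(trials_by_rate, t_start_s, n_rejected, n_trials)`` where
    ``trials_by_rate`` maps rate to analysis-windowed polarity-pair averages.
    Screening precedes pair averaging, as in the acquisition protocol.
    """
    cfg = blanking or BlankingConfig()
    fs = rec.sample_rate
    i_on = rec.onset_index
    template = build_templates(rec, channel) if template_subtraction else None
    out = {}
    t_start_s = None
    n_rej = n_tot = 0
    for rate in rec.rates:
        mask = np.isclose(rec.rate, rate)
        trials = rec.waveforms[mask, :, channel]
        pols = rec.polarity[mask]
        onsets = rec.onsets[float(rate)]
        cleaned = []
        for w, pol in zip(trials, pols):
            if template is not None:
                w = subtract_templates(w, template, onsets, fs, pol)
            if do_blanking:
                w = blank_interpolate(w, onsets, fs, cfg, rate_pps=float(rate))
            cleaned.append(w)
        cleaned = np.asarray(cleaned)
        kept, report = reject_outlier_trials(cleaned)
        kept_pols = pols[report.kept_index]
        n_rej += report.n_rejected
        n_tot += report.n_total
        pairs = polarity_pair_average(kept, kept_pols)
        win, start = analysis_window(pairs, fs, i_on)
        out[float(rate)] = win
        t_start_s = start / fs
        log.info(
            "rate %.1f pps: %d/%d trials kept, %d pairs",
            rate, report.n_total - report.n_rejected, report.n_total, len(win),
        )
    return out, t_start_s, n_rej, n_tot


def analyze_channel(
    trials_by_rate: dict,
    fs: float,
    t_start_s: float,
    channel: int,
    grid: GridSpec | None = None,
    gd_cfg: GroupDelayConfig | None = None,
    fit: bool = True,
    n_rejected: int = 0,
    n_trials: int = 0,
) -> ChannelResult:
    """Transfer function -> features -> model fit -> group delays."""
    gd_cfg = gd_cfg or GroupDelayConfig()
    tf = build_transfer_function(trials_by_rate, fs, t_start_s, channel)
    features = detect_peaks_dips(tf)
    model = fit_model(tf.rates_pps, tf.amplitude_uv, grid) if fit else None
    n_sig = int(tf.significant.sum())
    if n_sig >= 3:
        curve = phase_curve_from_tf(tf)
        segments = piecewise_fit(curve, gd_cfg)
        pw = segments_to_series(curve, segments)
        run3 = running_group_delay_3pt(curve, gd_cfg)
    else:
        warnings.warn("fewer than 3 significant rates; group delays unavailable")
        segments, pw, run3 = [], DelaySeries(np.array([]), np.array([]), "piecewise"), DelaySeries(np.array([]), np.array([]), "running3")
    max_sync = {
        "piecewise": max_sync_rates(pw, min_delay_ms=gd_cfg.min_delay_ms),
        "running3": max_sync_rates(run3, min_delay_ms=gd_cfg.min_delay_ms),
    }
    return ChannelResult(
        channel=channel,
        tf=tf,
        features=features,
        fit=model,
        segments=segments,
        piecewise=pw,
        running=run3,
        max_sync=max_sync,
        n_rejected=n_rejected,
        n_trials=max(n_trials, 1),
    )


def run_session(
    config: dict | None = None,
    seed: int = 0,
    recording: RecordingSet | None = None,
    fit: bool = True,
) -> SessionReport:
    """Execute a full analysis session.

    Either synthesize a recording from the config's ``synthesis`` block (with
    ``seed``) or analyze a supplied ``recording``.  Deterministic for a fixed
    seed and config.
    """
    config = config or {}
    if recording is None:
        spec, truth, artifact, noise = session_spec_from_config(config)
        log.info("synthesizing session: %d rates x %d trials", len(spec.pulse_rates), spec.n_trials_per_rate)
        recording = synth_session(spec, truth, artifact, noise, seed=seed)
    blank_cfg = BlankingConfig(**config.get("artifact", {}))
    gd_cfg = GroupDelayConfig(**config.get("group_delay", {}))
    channels = []
    for ch in (0, 1):
        trials, t_start, n_rej, n_tot = prepare_trials(recording, ch, blank_cfg)
        channels.append(
            analyze_channel(
                trials, recording.sample_rate, t_start, ch,
                gd_cfg=gd_cfg, fit=fit, n_rejected=n_rej, n_trials=n_tot,
            )
        )
    return SessionReport(channels=channels, config=config, seed=seed)


def intersession_reliability(
    sessions_by_subject: dict[str, list[FeatureSet]],
    tol_pps: float = 32.0,
    n_perm: int = 200,
    seed: int = 0,
    percentile: float = 95.0,
) -> dict:
    """Within-subject feature reproducibility against a between-subject null.

    For each subject, the first (representative) feature set is compared with
    each later session via :func:`match_features`; the observed hit rate
    aggregates hits over all comparisons.  The null distribution re-draws
    each comparison's counterpart from a random *different* subject's
    sessions (with replacement, ``n_perm`` permutations); its
    ``percentile``-th percentile is reported.
    """
    subjects = [s for s, fs in sessions_by_subject.items() if len(fs) >= 2]
    if not subjects:
        raise ValueError("need at least one subject with >= 2 sessions")
    comparisons = []  # (subject, representative, other)
    for s in subjects:
        rep, *rest = sessions_by_subject[s]
        for other in rest:
            comparisons.append((s, rep, other))
    obs_hits = obs_n = 0
    per_pair = []
    for s, rep, other in comparisons:
        m = match_features(rep, other, tol_pps)
        per_pair.append({"subject": s, "hit_rate": m.hit_rate, "n": m.n_features})
        obs_hits += m.n_hits
        obs_n += m.n_features
    observed = obs_hits / obs_n if obs_n else math.nan

    null_percentile = math.nan
    if len(sessions_by_subject) >= 2:
        rng = np.random.default_rng(seed)
        all_subjects = list(sessions_by_subject)
        null_rates = []
        for _ in range(n_perm):
            hits = n = 0
            for s, rep, _ in comparisons:
                pool = [x for x in all_subjects if x != s]
                o_subj = pool[rng.integers(len(pool))]
                cand = sessions_by_subject[o_subj]
                other = cand[rng.integers(len(cand))]
                m = match_features(rep, other, tol_pps)
                hits += m.n_hits
                n += m.n_features
            null_rates.append(hits / n if n else math.nan)
        null_percentile = float(np.nanpercentile(null_rates, percentile))
    else:
        warnings.warn("fewer than 2 subjects; permutation null undefined")
    return {
        "per_pair": per_pair,
        "observed_hit_rate": observed,
        "null_percentile": null_percentile,
        "n_perm": n_perm,
    }
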