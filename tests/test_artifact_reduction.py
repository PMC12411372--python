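"""Template subtraction, blanking, polarity averaging, and the sweep."""

import numpy as np
import pytest

from effr.artifact_reduction import (
    UPSAMPLE,
    ArtifactTemplate,
    BlankingConfig,
    _subtract_upsampled,
    blank_interpolate,
    build_templates,
    downsample_x10,
    polarity_pair_average,
    subtract_templates,
    upsample_x10,
)
from effr.synthetic_data import (
    ArtifactSpec,
    GeneratorGroundTruth,
    NeuralGenerator,
    NoiseSpec,
    StimulusSpec,
    artifact_waveform,
    make_rate_list,
    synth_session,
)

from .conftest import FS


class TestUpsample:
    def test_constant(self):
        up = upsample_x10(np.full(64, 2.5), FS)
        assert up.size == 640
        assert np.allclose(up, 2.5, atol=1e-9)

    def test_sinusoid_interpolation(self):
        # 100 Hz with an integer number of cycles at fs = 24000
        fs = 24000.0
        n = 240
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 100 * t)
        up = upsample_x10(x, fs)
        t10 = np.arange(n * 10) / (fs * 10)
        assert np.abs(up - np.sin(2 * np.pi * 100 * t10)).max() < 1e-6

    def test_round_trip_identity(self):
        x = np.random.default_rng(0).standard_normal(18310)
        assert np.abs(downsample_x10(upsample_x10(x, FS)) - x).max() < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            upsample_x10(np.array([]), FS)


def _artifact_only_recording(n_trials=4, rates=None, **art_kw):
    rates = rates or tuple(make_rate_list(FS, 150, 300, 6))
    spec = StimulusSpec(pulse_rates=rates, n_trials_per_rate=n_trials)
    truth = GeneratorGroundTruth((NeuralGenerator("G", 5.0, (0.0, 0.0)),))
    art = ArtifactSpec(**{"gain_jitter": 0, "time_jitter_samples": 0, **art_kw})
    return synth_session(spec, truth, art, NoiseSpec(rms_uv=0, burst_prob=0), seed=9), art


class TestTemplates:
    def test_pure_artifact_recovers_polarity_templates(self):
        rec, art = _artifact_only_recording()
        tpl = build_templates(rec, 0)
        # sign convention: anodic ~ -cathodic, near-perfect anticorrelation
        r = np.corrcoef(tpl.anodic, tpl.cathodic)[0, 1]
        assert r < -0.99
        # template matches the designed artifact sampled at the x10 rate
        t10 = np.arange(tpl.n_samples) / tpl.sample_rate_x10
        designed = artifact_waveform(t10, art)
        scale = (1 + (1 - art.polarity_asymmetry)) / 2  # common-mode removal
        assert np.corrcoef(tpl.anodic, designed)[0, 1] > 0.99

    def test_common_neural_component_removed_exactly(self):
        """A polarity-invariant signal added to every trial cancels from the
        templates to machine precision (linearity of the construction)."""
        rec, _ = _artifact_only_recording()
        tpl0 = build_templates(rec, 0)
        rng = np.random.default_rng(4)
        common = rng.standard_normal(rec.waveforms.shape[1]) * 50.0
        rec.waveforms[:, :, 0] += common[None, :]
        tpl1 = build_templates(rec, 0)
        ref = np.abs(tpl0.anodic).max()
        assert np.abs(tpl1.anodic - tpl0.anodic).max() < 1e-9 * ref
        assert np.abs(tpl1.cathodic - tpl0.cathodic).max() < 1e-9 * ref

    def test_missing_polarity_rejected(self):
        rec, _ = _artifact_only_recording()
        rec.polarity[:] = 1
        with pytest.raises(ValueError):
            build_templates(rec, 0)


class TestSubtraction:
    def _template(self):
        n = int(round(1400e-6 * FS * UPSAMPLE))
        t10 = np.arange(n) / (FS * UPSAMPLE)
        return artifact_waveform(t10, ArtifactSpec())

    def test_self_subtraction_residual(self):
        """A trial that is exactly a train of templates is annihilated."""
        tpl = self._template()
        spp10 = 160 * UPSAMPLE
        x10 = np.zeros(spp10 * 20)
        onsets10 = np.arange(0, x10.size - tpl.size, spp10)
        for o in onsets10:
            x10[o : o + tpl.size] += tpl
        out = _subtract_upsampled(x10, tpl, onsets10)
        assert np.linalg.norm(out) < 1e-9 * np.linalg.norm(x10)

    def test_per_pulse_gain_absorbed(self):
        tpl = self._template()
        spp10 = 160 * UPSAMPLE
        gains = [0.9, 1.0, 1.1] * 5
        x10 = np.zeros(spp10 * 16)
        onsets10 = np.arange(0, spp10 * 15, spp10)
        for g, o in zip(gains, onsets10):
            x10[o : o + tpl.size] += g * tpl
        out = _subtract_upsampled(x10, tpl, onsets10)
        assert np.linalg.norm(out) < 1e-9 * np.linalg.norm(x10)

    def test_global_shift_aligned(self):
        """A +1-original-sample shift is found by the alignment search."""
        tpl = self._template()
        spp10 = 160 * UPSAMPLE
        x10 = np.zeros(spp10 * 16)
        onsets10 = np.arange(0, spp10 * 15, spp10)
        for o in onsets10:
            x10[o + UPSAMPLE : o + UPSAMPLE + tpl.size] += tpl
        with pytest.warns(UserWarning, match="search bound"):
            out = _subtract_upsampled(x10, tpl, onsets10)
        assert np.linalg.norm(out) < 1e-6 * np.linalg.norm(x10)

    def test_full_rate_path(self):
        """subtract_templates at the original rate removes a band-limited
        artifact train built from the same interpolation."""
        rec, _ = _artifact_only_recording(n_trials=2)
        tpl = build_templates(rec, 0)
        rate = rec.rates[0]
        onsets = rec.onsets[float(rate)]
        w = rec.select(rate, polarity=1)[0][:, 0]
        out = subtract_templates(w, tpl, onsets, FS, polarity=1)
        assert np.sqrt(np.mean(out**2)) < 0.02 * np.sqrt(np.mean(w**2))


class TestBlanking:
    def test_linear_ramp_unchanged(self):
        x = np.linspace(0.0, 1.0, 4000)
        out = blank_interpolate(x, np.array([500, 1500, 2500]), FS)
        assert np.allclose(out, x, atol=1e-12)

    def test_impulse_in_window_removed(self):
        x = np.zeros(4000)
        o = 1000
        d = int(round(400e-6 * FS))
        x[o + d] = 5.0  # inside [50, 850] us after the onset
        out = blank_interpolate(x, np.array([o]), FS)
        assert np.all(out == 0.0)

    def test_boundary_samples_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        o = 1000
        cfg = BlankingConfig()
        out = blank_interpolate(x, np.array([o]), FS, cfg)
        d0 = int(round(cfg.blank_start_us * 1e-6 * FS))
        d1 = int(round((cfg.blank_start_us + cfg.blank_len_us) * 1e-6 * FS))
        assert out[o + d0 - 1] == x[o + d0 - 1]
        assert out[o + d1] == x[o + d1]
        assert np.array_equal(out[: o + d0 - 1], x[: o + d0 - 1])

    def test_blank_fraction_published_values(self):
        cfg = BlankingConfig()
        assert cfg.fraction_of_period(642.47) == pytest.approx(0.51, abs=0.01)
        assert cfg.fraction_of_period(42.98) == pytest.approx(0.034, abs=0.005)

    def test_whole_period_blank_rejected(self):
        cfg = BlankingConfig(blank_len_us=2000.0)
        with pytest.raises(ValueError):
            blank_interpolate(np.zeros(1000), np.array([100]), FS, cfg, rate_pps=642.47)


class TestPolarityAveraging:
    def test_pure_artifact_pair_cancels(self):
        a = np.sin(np.arange(100.0))
        trials = np.stack([a, -a])
        out = polarity_pair_average(trials, np.array([1, -1]))
        assert np.abs(out).max() < 1e-12

    def test_neural_content_preserved(self):
        a = np.sin(np.arange(100.0))
        n = np.cos(np.arange(100.0) / 7)
        trials = np.stack([n + a, n - a])
        out = polarity_pair_average(trials, np.array([1, -1]))
        assert np.allclose(out[0], n, atol=1e-12)

    def test_20_plus_20_yields_20(self):
        trials = np.zeros((40, 10))
        pols = np.array([1, -1] * 20)
        assert polarity_pair_average(trials, pols).shape[0] == 20

    def test_unpaired_excess_dropped_with_warning(self):
        trials = np.zeros((5, 10))
        pols = np.array([1, 1, 1, -1, -1])
        with pytest.warns(UserWarning, match="unpaired"):
            out = polarity_pair_average(trials, pols)
        assert out.shape[0] == 2


def test_artifact_energy_monotone_across_stages():
    """RMS within the post-pulse artifact window never increases from raw ->
    template-subtracted -> blanked -> polarity-averaged."""
    rec, _ = _artifact_only_recording(n_trials=4, gain_jitter=0.05)
    tpl = build_templates(rec, 0)
    rate = rec.rates[0]
    onsets = rec.onsets[float(rate)]
    trials = rec.select(rate)[:, :, 0]
    pols = rec.polarity[np.isclose(rec.rate, rate)]

    def window_rms(w):
        n = int(round(1400e-6 * FS))
        segs = [w[o : o + n] for o in onsets[:20]]
        return np.sqrt(np.mean(np.concatenate(segs) ** 2))

    raw = np.mean([window_rms(w) for w in trials])
    sub = np.array([subtract_templates(w, tpl, onsets, FS, p) for w, p in zip(trials, pols)])
    s1 = np.mean([window_rms(w) for w in sub])
    bl = np.array([blank_interpolate(w, onsets, FS) for w in sub])
    s2 = np.mean([window_rms(w) for w in bl])
    pa = polarity_pair_average(bl, pols)
    s3 = np.mean([window_rms(w) for w in pa])
    assert raw >= s1 >= s2 >= s3
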