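"""Synthetic EEG generator: kernels, noise, reproducibility, and file I/O."""

import hashlib

import numpy as np
import pytest

from gamblerp.edfwrite import quantization_step_uV, read_edf
from gamblerp.pipeline import average, baseline_correct, epoch
from gamblerp.simulate_eeg import (
    ComponentTemplate,
    NoiseModel,
    default_templates,
    read_recording,
    render_component,
    simulate_participant_epochs,
    synthesize_recording,
    write_recording,
)
from gamblerp.task import TaskParams, control_profile, simulate_session

SILENT = NoiseModel.silent()


def bump(amplitude=5.0, latency=250.0, jitter=0.0, name="P3a", width=44.0):
    pol = 1 if amplitude >= 0 else -1
    return ComponentTemplate(
        name, pol, "S", width, {ch: amplitude for ch in ("Fz", "Cz", "POz")},
        {(): latency}, latency_jitter_sd_ms=jitter,
    )


class TestRenderComponent:
    def test_extremum_at_mean_latency_without_jitter(self):
        k = render_component(bump(), "controls", "HF", "Cz")
        t = -500.0 + np.arange(len(k)) * 1000.0 / 1024.0
        assert t[np.argmax(k)] == pytest.approx(250.0, abs=1.0)
        assert k.max() == pytest.approx(5.0, rel=1e-6)

    def test_zero_amplitude_silent_channel(self):
        k = render_component(bump(), "controls", "HF", "Pz")  # not in amplitude map
        assert not k.any()

    def test_negative_polarity(self):
        k = render_component(bump(amplitude=-3.0), "controls", "HF", "Fz")
        assert k.min() == pytest.approx(-3.0, rel=1e-6)

    def test_jitter_sd_recovered(self):
        rng = np.random.default_rng(0)
        tpl = bump(jitter=20.0)
        t = -500.0 + np.arange(1536) * 1000.0 / 1024.0
        lats = []
        for _ in range(1000):
            k = render_component(tpl, "controls", "HF", "Cz", rng=rng)
            lats.append(t[np.argmax(k)])
        assert np.std(lats) == pytest.approx(20.0, rel=0.10)


class TestEpochGeneration:
    def test_noiseless_epochs_equal_summed_kernels(self, session_trials):
        trial = session_trials[:1]
        eps = simulate_participant_epochs(
            trial, noise=SILENT, trigger="S", group="controls", seed=0
        )
        expected = np.zeros_like(eps.data[0])
        for tpl in default_templates():
            if tpl.trigger != "S":
                continue
            for ci, ch in enumerate(eps.ch_names):
                tpl_nj = ComponentTemplate(
                    tpl.name, tpl.polarity, tpl.trigger, tpl.width_ms,
                    tpl.amplitude_uV, tpl.latency_ms, 0.0, tpl.amplitude_scale,
                )
                expected[ci] += render_component(tpl_nj, "controls", trial[0].condition, ch)
        # jitter is on, so allow the bump-displacement it causes
        assert np.corrcoef(eps.data.ravel(), expected.ravel())[0, 1] > 0.95

    def test_seeded_reproducibility(self, session_trials, quiet_noise):
        h = []
        for _ in range(2):
            eps = simulate_participant_epochs(session_trials, noise=quiet_noise, seed=42)
            h.append(hashlib.sha256(eps.data.tobytes()).hexdigest())
        assert h[0] == h[1]
        eps2 = simulate_participant_epochs(session_trials, noise=quiet_noise, seed=43)
        assert hashlib.sha256(eps2.data.tobytes()).hexdigest() != h[0]

    def test_amplitude_linearity_of_average(self, session_trials):
        """Doubling template amplitudes doubles the noiseless average."""
        def avg(scale):
            tpls = [
                ComponentTemplate(
                    t.name, t.polarity, t.trigger, t.width_ms,
                    {ch: a * scale for ch, a in t.amplitude_uV.items()},
                    t.latency_ms, 0.0, t.amplitude_scale,
                )
                for t in default_templates()
            ]
            eps = simulate_participant_epochs(
                session_trials, templates=tpls, noise=SILENT, seed=1
            )
            return average(eps, "HF").mean

        assert np.allclose(avg(2.0), 2.0 * avg(1.0), atol=1e-9)

    def test_group_condition_amplitude_scaling(self):
        tpl = bump()
        tpl = ComponentTemplate(
            tpl.name, tpl.polarity, tpl.trigger, tpl.width_ms, tpl.amplitude_uV,
            tpl.latency_ms, 0.0, {("ADHD", "HF"): 2.0},
        )
        k_scaled = render_component(tpl, "ADHD", "HF", "Cz")
        k_plain = render_component(tpl, "ADHD", "LF", "Cz")
        assert k_scaled.max() == pytest.approx(2 * k_plain.max())


class TestContinuousSynthesis:
    def test_noiseless_roundtrip_through_epoching(self, session_trials):
        trials = session_trials[:48]
        rec = synthesize_recording(trials, noise=SILENT, seed=0)
        erp = average(baseline_correct(epoch(rec, "S")), "HF")
        eps_direct = simulate_participant_epochs(trials, noise=SILENT, seed=0)
        erp_direct = average(baseline_correct(eps_direct), "HF")
        # same planted structure either route (jitter draws differ)
        r = np.corrcoef(erp.mean.ravel(), erp_direct.mean.ravel())[0, 1]
        assert r > 0.98

    def test_event_annotations_complete(self, session_trials):
        rec = synthesize_recording(session_trials[:16], noise=SILENT, seed=0)
        assert len(rec.events) == 32
        assert {e.trigger for e in rec.events} == {"S", "I"}

    def test_epoch_snr_matches_power_budget(self, session_trials):
        """Per-epoch evoked/noise power ratio tracks the configured scales."""
        noise = NoiseModel(
            pink_noise_scale_uV=8.0, alpha_amp_uV=0.0, blink_rate_per_min=0.0,
            blink_amp_uV=0.0, muscle_burst_rate_per_min=0.0, muscle_amp_uV=0.0,
            sensor_sd_uV=0.0,
        )
        trials = session_trials[:32]
        sig = simulate_participant_epochs(trials, noise=SILENT, seed=3)
        noisy = simulate_participant_epochs(trials, noise=noise, seed=3)
        noise_part = noisy.data - sig.data
        measured = noise_part.std()
        assert measured == pytest.approx(8.0, rel=0.20)


class TestRecordingIO:
    @pytest.fixture()
    def recording(self, session_trials, quiet_noise):
        return synthesize_recording(session_trials[:8], noise=quiet_noise, seed=5)

    def test_matrix_roundtrip_bitwise(self, recording, tmp_path):
        write_recording(recording, tmp_path / "rec", format="matrix")
        back = read_recording(tmp_path / "rec", format="matrix")
        assert np.array_equal(back.data, recording.data.astype("<f4").astype(float))
        assert back.fs == recording.fs and back.ch_names == recording.ch_names
        assert back.events == recording.events

    def test_edf_roundtrip_within_quantization(self, recording, tmp_path):
        write_recording(recording, tmp_path / "rec", format="edf")
        back = read_edf(tmp_path / "rec.edf")
        step = quantization_step_uV(recording.data)
        n = recording.n_samples
        assert np.abs(back.data[:, :n] - recording.data).max() <= step
        assert len(back.events) == len(recording.events)
        for a, b in zip(back.events, recording.events):
            assert a.trigger == b.trigger and a.condition == b.condition
            assert a.onset_s == pytest.approx(b.onset_s, abs=1e-6)

    def test_edf_readable_by_mne(self, recording, tmp_path):
        """Independent reader oracle: MNE parses our EDF+ to the same samples."""
        mne = pytest.importorskip("mne")
        write_recording(recording, tmp_path / "rec", format="edf")
        raw = mne.io.read_raw_edf(tmp_path / "rec.edf", preload=True, verbose="error")
        data_uV = raw.get_data(units="uV")
        step = quantization_step_uV(recording.data)
        n = recording.n_samples
        assert list(raw.ch_names) == list(recording.ch_names)
        assert np.abs(data_uV[:, :n] - recording.data).max() <= 1.5 * step
        onsets = sorted(a["onset"] for a in raw.annotations)
        expected = sorted(e.onset_s for e in recording.events)
        assert onsets == pytest.approx(expected, abs=1e-3)

    def test_empty_event_list(self, tmp_path):
        from gamblerp.pipeline import CHANNELS, Recording

        rec = Recording(
            data=np.random.default_rng(0).normal(size=(6, 2048)),
            fs=1024.0, ch_names=CHANNELS, events=[],
        )
        write_recording(rec, tmp_path / "empty", format="edf")
        back = read_edf(tmp_path / "empty.edf")
        assert back.events == []
        write_recording(rec, tmp_path / "empty", format="matrix")
        assert read_recording(tmp_path / "empty", format="matrix").events == []

    def test_unknown_format_rejected(self, recording, tmp_path):
        with pytest.raises(ValueError):
            write_recording(recording, tmp_path / "x", format="fif")
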