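"""HF-LF difference waves, group envelopes, and windowed statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamblerp.differential import (
    BandCurve,
    DifferenceWave,
    band_separation,
    band_separation_test,
    difference_wave,
    group_band,
    window_amplitude_profile,
)
from gamblerp.pipeline import CHANNELS, ERPWaveform

FS = 1024.0
N = 1536


def erp(curve, condition, participant=0, trigger="S"):
    return ERPWaveform(
        mean=np.tile(np.asarray(curve, dtype=float), (len(CHANNELS), 1)),
        n_epochs=80, fs=FS, trigger=trigger, condition=condition, participant=participant,
    )


def diff_from(curve, participant=0, group="controls"):
    return DifferenceWave(
        curve=np.tile(np.asarray(curve, dtype=float), (len(CHANNELS), 1)),
        fs=FS, trigger="S", participant=participant, group=group,
    )


class TestDifferenceWave:
    def test_identical_inputs_zero_curve(self):
        base = np.random.default_rng(0).normal(size=N)
        d = difference_wave(erp(base, "HF"), erp(base, "LF"))
        assert not d.curve.any()

    def test_constant_shift(self):
        base = np.random.default_rng(1).normal(size=N)
        d = difference_wave(erp(base + 3.0, "HF"), erp(base, "LF"))
        assert np.allclose(d.curve, 3.0)

    def test_mismatched_participants_rejected(self):
        with pytest.raises(ValueError):
            difference_wave(erp(np.zeros(N), "HF", participant=0),
                            erp(np.zeros(N), "LF", participant=1))

    def test_condition_specific_component_localised(self, session_trials):
        """With only a condition-dependent N500, the difference wave is
        confined to the N500 support."""
        from gamblerp.pipeline import average, baseline_correct
        from gamblerp.simulate_eeg import (
            ComponentTemplate, NoiseModel, simulate_participant_epochs,
        )

        tpl = ComponentTemplate(
            "N500", -1, "S", 100.0, {"Fz": -3.0}, {(): 490.0}, 0.0,
            {("controls", "HF"): 1.5, ("controls", "LF"): 0.5},
        )
        eps = simulate_participant_epochs(
            session_trials, templates=[tpl], noise=NoiseModel.silent(), seed=0
        )
        eps = baseline_correct(eps)
        d = difference_wave(average(eps, "HF"), average(eps, "LF"))
        t = d.times_ms
        inside = np.abs(t - 490.0) < 150.0
        fz = d.channel("Fz")
        assert np.abs(fz[~inside]).max() < 0.05 * np.abs(fz[inside]).max()


class TestGroupBand:
    def test_identical_curves_zero_width(self):
        base = np.random.default_rng(2).normal(size=N)
        band = group_band([diff_from(base, participant=i) for i in range(5)])
        assert np.allclose(band.upper_curve, band.lower_curve)
        assert np.allclose(band.mean_curve, base)

    def test_antisymmetric_pair_closed_form(self):
        c = np.abs(np.random.default_rng(3).normal(size=N)) + 0.1
        band = group_band([diff_from(c, 0), diff_from(-c, 1)])
        assert np.allclose(band.mean_curve, 0.0)
        # sample SD of {c, -c} is c*sqrt(2); SEM = c*sqrt(2)/sqrt(2) = c
        assert np.allclose(band.upper_curve, np.tile(c, (len(CHANNELS), 1)))

    def test_band_width_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(4)
        pool = [diff_from(rng.normal(size=N), i) for i in range(64)]
        w16 = (group_band(pool[:16]).upper_curve - group_band(pool[:16]).lower_curve).mean()
        w64 = (group_band(pool).upper_curve - group_band(pool).lower_curve).mean()
        assert w64 == pytest.approx(w16 / 2.0, rel=0.15)

    def test_single_curve_rejected(self):
        with pytest.raises(ValueError):
            group_band([diff_from(np.zeros(N))])


class TestBandSeparation:
    def band_pair(self, offset):
        rng = np.random.default_rng(5)
        base = [diff_from(rng.normal(size=N), i) for i in range(8)]
        shifted = [diff_from(d.curve[0] + offset, i) for i, d in enumerate(base)]
        return group_band(base), group_band(shifted)

    def test_identical_groups_zero(self):
        a, _ = self.band_pair(0.0)
        assert band_separation(a, a, 260.0) == 0.0

    def test_constant_offset_zero_width_closed_form(self):
        k, w = 2.5, 50.0
        flat = [diff_from(np.zeros(N), i) for i in range(4)]
        raised = [diff_from(np.full(N, k), i) for i in range(4)]
        stat = band_separation(group_band(raised), group_band(flat), 260.0, half_width_ms=w)
        assert stat == pytest.approx(k * 2 * w, rel=0.02)

    @given(offset=st.floats(-4.0, 4.0))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_antisymmetry(self, offset):
        a, b = self.band_pair(offset)
        assert band_separation(a, b, 260.0) == pytest.approx(
            -band_separation(b, a, 260.0), abs=1e-9
        )

    def test_never_exceeds_mean_distance(self):
        a, b = self.band_pair(1.5)
        stat = abs(band_separation(a, b, 260.0))
        t = a.times_ms
        mask = np.abs(t - 260.0) <= 50.0
        i = a._idx("Fz")
        bound = np.trapezoid(
            np.abs(a.mean_curve[i] - b.mean_curve[i])[mask], t[mask]
        )
        assert stat <= bound + 1e-9

    def test_permutation_test_flags_planted_offset(self):
        rng = np.random.default_rng(6)
        a = [diff_from(rng.normal(0, 0.3, N), i) for i in range(10)]
        b = [diff_from(rng.normal(3.0, 0.3, N), i) for i in range(10)]
        ws = band_separation_test(a, b, 260.0, n_perm=199, seed=0)
        assert ws.significant_nonzero and ws.statistic < 0


class TestWindowAmplitudeProfile:
    def test_zero_curves_degenerate_point_ci(self):
        diffs = [diff_from(np.zeros(N), i) for i in range(6)]
        with pytest.raises(ValueError):
            # all-zero integrals: the signed-rank test degenerates, but the
            # profile itself must still report a collapsed CI
            from gamblerp.stats import wilcoxon_signed
            wilcoxon_signed([0.0] * 6)
        stats = window_amplitude_profile(diffs, 260.0, n_boot=200, seed=0)
        ws = stats["Fz"]
        assert ws.statistic == 0.0 and ws.ci_low == 0.0 and ws.ci_high == 0.0
        assert ws.degenerate and not ws.significant_nonzero

    def test_constant_effect_closed_form(self):
        diffs = [diff_from(np.full(N, 2.0), i) for i in range(6)]
        stats = window_amplitude_profile(diffs, 260.0, half_width_ms=50.0, n_boot=100, seed=0)
        assert stats["Cz"].statistic == pytest.approx(2.0 * 100.0, rel=0.02)

    def test_planted_shift_significant(self):
        rng = np.random.default_rng(7)
        diffs = [diff_from(rng.normal(1.0, 0.2, N), i) for i in range(12)]
        stats = window_amplitude_profile(diffs, 260.0, n_boot=500, seed=1)
        assert stats["Pz"].significant_nonzero
        assert stats["Pz"].ci_low <= stats["Pz"].statistic <= stats["Pz"].ci_high

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            window_amplitude_profile([diff_from(np.zeros(N))] * 4, 260.0)


def test_window_group_comparison_detects_planted_shift():
    from gamblerp.differential import window_group_comparison

    rng = np.random.default_rng(8)
    a = [diff_from(rng.normal(0.0, 0.3, N), i) for i in range(10)]
    b = [diff_from(rng.normal(2.0, 0.3, N), i) for i in range(10)]
    res = window_group_comparison(a, b, 260.0)
    assert res.p_value < 0.01
    null = window_group_comparison(a, a, 260.0)
    assert null.p_value > 0.9
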