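"""Synthetic EEG with planted ERP components for the gambling task.

Each simulated participant's brain response is a sum of Gaussian-bump
components time-locked to the two trial events — trial onset ``S``
(premotor build-up M, visual C1, the N2-P3a orienting complex, P3b, and a
feedback-frequency-sensitive N500) and gamble selection ``I`` (N2, P3a,
P3b, an N400-like wave, and a late positive potential LPP).  Component
mean latencies are parameterised per (group, condition, ROI) and default
to the study's group medians, so the generator plants the group and
condition latency shifts the analysis pipeline is meant to recover.

On top of the evoked signal the generator adds 1/f (pink) background
noise, a ~10 Hz alpha rhythm, frontally weighted blinks, brief muscle
bursts, and white sensor noise.  Epoch stacks can be produced directly
(fast path for simulations) or a continuous recording with annotated
events can be synthesised and written to disk (raw matrix + JSON sidecar,
or 16-bit EDF+ with annotations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pipeline import (
    CHANNELS,
    EPOCH_WINDOW_MS,
    FRONTOCENTRAL,
    EpochSet,
    Event,
    Recording,
    window_samples,
)
from .task import TrialRecord

__all__ = [
    "ComponentTemplate",
    "NoiseModel",
    "default_templates",
    "render_component",
    "simulate_participant_epochs",
    "synthesize_recording",
    "write_recording",
    "read_recording",
]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))

ROI_OF = {ch: ("frontocentral" if ch in FRONTOCENTRAL else "centroparietal") for ch in CHANNELS}


@dataclass(frozen=True)
class ComponentTemplate:
    """One named ERP component as a Gaussian bump.

    ``latency_ms`` maps a key to the mean peak latency relative to the
    trigger; keys are matched most-specific first: (group, condition, roi),
    (group, condition), (condition,), then ().  ``amplitude_uV`` gives the
    signed peak per electrode (already polarity-signed); electrodes absent
    from the map do not express the component.  ``width_ms`` is the full
    width at half maximum of the bump.  ``amplitude_scale`` optionally
    scales the amplitude per (group, condition[, roi]) key — the hook for
    planting group-by-condition amplitude effects.
    """

    name: str
    polarity: int
    trigger: str
    width_ms: float
    amplitude_uV: dict[str, float]
    latency_ms: dict[tuple, float]
    latency_jitter_sd_ms: float = 20.0
    amplitude_scale: dict[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        for ch, a in self.amplitude_uV.items():
            if a != 0 and np.sign(a) != self.polarity:
                raise ValueError(f"{self.name}@{ch}: amplitude sign contradicts polarity")

    def mean_latency(self, group: str, condition: str, electrode: str) -> float:
        roi = ROI_OF.get(electrode)
        for key in ((group, condition, roi), (group, condition), (condition,), ()):
            if key in self.latency_ms:
                return self.latency_ms[key]
        raise KeyError(f"{self.name}: no latency for {(group, condition, electrode)}")

    def scale(self, group: str, condition: str, electrode: str) -> float:
        roi = ROI_OF.get(electrode)
        for key in ((group, condition, roi), (group, condition), (condition,), ()):
            if key in self.amplitude_scale:
                return self.amplitude_scale[key]
        return 1.0


def _taper(**per_channel: float) -> dict[str, float]:
    return {ch: per_channel[ch] for ch in CHANNELS if ch in per_channel}


def default_templates() -> list[ComponentTemplate]:
    """Templates calibrated to the study's median component latencies.

    N2/P3a/P3b latencies carry the full (group, condition, ROI) structure
    of the reported medians for both triggers; C1, M, N500, N400-like and
    LPP sit at their described latencies.  Amplitudes are free parameters
    of the generator (no group-level amplitudes were reported); the
    topographic tapers follow the described scalp distributions (C1
    posterior, N500 frontal, N400-like central, LPP centroparietal).
    """
    C, A, fc, cp = "controls", "ADHD", "frontocentral", "centroparietal"

    def lat(fc_vals, cp_vals):
        # vals order: (controls, HF), (ADHD, HF), (controls, LF), (ADHD, LF)
        out = {}
        for roi, (chf, ahf, clf, alf) in ((fc, fc_vals), (cp, cp_vals)):
            out[(C, "HF", roi)] = chf
            out[(A, "HF", roi)] = ahf
            out[(C, "LF", roi)] = clf
            out[(A, "LF", roi)] = alf
        return out

    return [
        ComponentTemplate(
            "M", -1, "S", 100.0,
            _taper(Fz=-1.0, FCz=-1.5, Cz=-2.0, CPz=-1.5, Pz=-1.0, POz=-0.5),
            {(): -150.0},
        ),
        ComponentTemplate(
            "C1", 1, "S", 30.0,
            _taper(Pz=2.0, POz=2.5),
            {(): 70.0},
            latency_jitter_sd_ms=8.0,
        ),
        ComponentTemplate(
            "N2", -1, "S", 40.0,
            _taper(Fz=-4.0, FCz=-4.5, Cz=-4.0, CPz=-4.0, Pz=-3.5, POz=-3.0),
            lat((164.0, 173.5, 171.0, 174.0), (190.5, 179.0, 189.5, 187.0)),
            latency_jitter_sd_ms=15.0,
        ),
        ComponentTemplate(
            "P3a", 1, "S", 44.0,
            _taper(Fz=5.0, FCz=6.0, Cz=6.0, CPz=5.5, Pz=5.0, POz=4.0),
            lat((246.5, 243.0, 262.0, 247.0), (251.0, 255.5, 264.0, 260.0)),
            latency_jitter_sd_ms=15.0,
        ),
        ComponentTemplate(
            "P3b", 1, "S", 60.0,
            _taper(Fz=3.5, FCz=4.0, Cz=4.5, CPz=5.0, Pz=5.5, POz=5.0),
            lat((351.0, 349.0, 356.0, 363.5), (353.0, 348.0, 357.0, 354.0)),
            latency_jitter_sd_ms=15.0,
        ),
        ComponentTemplate(
            "N500", -1, "S", 100.0,
            _taper(Fz=-3.0, FCz=-2.5, Cz=-2.0, CPz=-1.2, Pz=-0.8, POz=-0.5),
            {(): 490.0},
            # larger frontal N500 during HF trials in the ADHD group
            amplitude_scale={(A, "HF"): 1.25, (A, "LF"): 0.8},
        ),
        ComponentTemplate(
            "N2", -1, "I", 40.0,
            _taper(Fz=-4.0, FCz=-4.5, Cz=-4.0, CPz=-4.0, Pz=-3.5, POz=-3.0),
            lat((167.5, 174.0, 165.0, 174.5), (178.5, 181.0, 178.0, 184.0)),
            latency_jitter_sd_ms=15.0,
        ),
        ComponentTemplate(
            "P3a", 1, "I", 44.0,
            _taper(Fz=5.0, FCz=6.0, Cz=6.0, CPz=5.5, Pz=5.0, POz=4.0),
            lat((235.0, 242.0, 237.5, 245.0), (244.0, 245.0, 239.5, 251.5)),
            latency_jitter_sd_ms=15.0,
        ),
        ComponentTemplate(
            "P3b", 1, "I", 60.0,
            _taper(Fz=3.5, FCz=4.0, Cz=4.5, CPz=5.0, Pz=5.5, POz=5.0),
            lat((351.0, 342.0, 360.0, 350.5), (360.0, 350.5, 370.5, 362.0)),
            latency_jitter_sd_ms=15.0,
        ),
        ComponentTemplate(
            "N400_like", -1, "I", 100.0,
            _taper(Fz=-2.0, FCz=-2.5, Cz=-3.0, CPz=-2.5, Pz=-1.5, POz=-1.0),
            {(): 490.0},
            # deeper post-choice negativity during LF trials in ADHD
            amplitude_scale={(A, "LF"): 1.25, (A, "HF"): 0.85},
        ),
        ComponentTemplate(
            "LPP", 1, "I", 150.0,
            _taper(Fz=1.0, FCz=1.5, Cz=2.0, CPz=2.5, Pz=2.5, POz=2.0),
            {(): 850.0},
        ),
    ]


@dataclass(frozen=True)
class NoiseModel:
    """Additive background activity and artifacts, all amplitudes in µV."""

    pink_noise_scale_uV: float = 8.0
    alpha_amp_uV: float = 3.0
    alpha_freq_hz: float = 10.0
    blink_rate_per_min: float = 4.0
    blink_amp_uV: float = 150.0
    muscle_burst_rate_per_min: float = 2.0
    muscle_amp_uV: float = 25.0
    sensor_sd_uV: float = 2.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 10.0, 0.0, 0.0, 0.0, 0.0, 0.0)


#: Frontally weighted blink projection onto the midline channels.
BLINK_TOPO = {"Fz": 1.0, "FCz": 0.8, "Cz": 0.6, "CPz": 0.4, "Pz": 0.3, "POz": 0.2}


def _gauss(t_ms: np.ndarray, center_ms, fwhm_ms: float) -> np.ndarray:
    sd = fwhm_ms / _FWHM_TO_SD
    return np.exp(-0.5 * ((t_ms - center_ms) / sd) ** 2)


def render_component(
    template: ComponentTemplate,
    group: str,
    condition: str,
    electrode: str,
    rng: np.random.Generator | None = None,
    fs: float = 1024.0,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
) -> np.ndarray:
    """One single-trial kernel over the epoch window, µV.

    The bump peaks at the template's mean latency plus one jitter draw
    (omit ``rng`` for a jitter-free render); the extremum equals the
    electrode's signed amplitude.  Electrodes without an amplitude entry
    yield an all-zero kernel.
    """
    n = window_samples(fs, window_ms)
    t = window_ms[0] + np.arange(n) * 1000.0 / fs
    amp = template.amplitude_uV.get(electrode, 0.0) * template.scale(group, condition, electrode)
    if amp == 0.0:
        return np.zeros(n)
    center = template.mean_latency(group, condition, electrode)
    if rng is not None and template.latency_jitter_sd_ms > 0:
        center += rng.normal(0.0, template.latency_jitter_sd_ms)
    return amp * _gauss(t, center, template.width_ms)


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float, scale: float) -> np.ndarray:
    """1/f-power noise along the last axis, unit-SD scaled to ``scale`` µV."""
    n = shape[-1]
    white = rng.standard_normal(shape, dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    nz = freqs > 0
    gain[nz] = 1.0 / np.sqrt(freqs[nz])
    spec *= gain
    pink = np.fft.irfft(spec, n=n, axis=-1)
    sd = float(pink.std())
    return pink * (scale / sd) if sd > 0 else pink


def _noise_block(
    noise: NoiseModel,
    rng: np.random.Generator,
    n_epochs: int,
    ch_names: tuple[str, ...],
    n_samp: int,
    fs: float,
) -> np.ndarray:
    """Background + artifacts for a stack of independent epochs."""
    n_ch = len(ch_names)
    out = np.zeros((n_epochs, n_ch, n_samp))
    if noise.pink_noise_scale_uV > 0:
        out += _pink_noise(rng, (n_epochs, n_ch, n_samp), fs, noise.pink_noise_scale_uV)
    if noise.alpha_amp_uV > 0:
        t = np.arange(n_samp, dtype=np.float32) / np.float32(fs)
        phase = rng.uniform(0, 2 * np.pi, (n_epochs, n_ch, 1)).astype(np.float32)
        amp = noise.alpha_amp_uV * rng.uniform(0.5, 1.5, (n_epochs, n_ch, 1))
        out += amp * np.sin(2 * np.float32(np.pi) * np.float32(noise.alpha_freq_hz) * t + phase)
    if noise.sensor_sd_uV > 0:
        out += noise.sensor_sd_uV * rng.standard_normal((n_epochs, n_ch, n_samp), dtype=np.float32)
    t_ms = np.arange(n_samp) * 1000.0 / fs
    epoch_min = n_samp / fs / 60.0  # epoch length in minutes
    if noise.blink_amp_uV > 0 and noise.blink_rate_per_min > 0:
        n_blinks = rng.poisson(noise.blink_rate_per_min * epoch_min, n_epochs)
        topo = np.array([BLINK_TOPO.get(ch, 0.3) for ch in ch_names])
        for i in np.nonzero(n_blinks)[0]:
            for _ in range(n_blinks[i]):
                center = rng.uniform(0, t_ms[-1])
                bump = noise.blink_amp_uV * _gauss(t_ms, center, 250.0)
                out[i] += topo[:, None] * bump
    if noise.muscle_amp_uV > 0 and noise.muscle_burst_rate_per_min > 0:
        n_bursts = rng.poisson(noise.muscle_burst_rate_per_min * epoch_min, n_epochs)
        for i in np.nonzero(n_bursts)[0]:
            for _ in range(n_bursts[i]):
                ch = rng.integers(n_ch)
                center = rng.uniform(0, t_ms[-1])
                envelope = _gauss(t_ms, center, 100.0)
                out[i, ch] += noise.muscle_amp_uV * envelope * rng.standard_normal(n_samp)
    return out


def _evoked_epochs(
    conditions: np.ndarray,
    templates: list[ComponentTemplate],
    trigger: str,
    group: str,
    rng: np.random.Generator | None,
    ch_names: tuple[str, ...],
    n_samp: int,
    fs: float,
    window_ms: tuple[float, float],
) -> np.ndarray:
    """Planted-component signal per epoch; one jitter draw per component
    per trial, shared across electrodes (a component peaks together over
    the scalp)."""
    t = window_ms[0] + np.arange(n_samp) * 1000.0 / fs
    n_epochs = len(conditions)
    out = np.zeros((n_epochs, len(ch_names), n_samp))
    for tpl in templates:
        if tpl.trigger != trigger:
            continue
        jitter = (
            rng.normal(0.0, tpl.latency_jitter_sd_ms, n_epochs)
            if rng is not None and tpl.latency_jitter_sd_ms > 0
            else np.zeros(n_epochs)
        )
        for ci, ch in enumerate(ch_names):
            base_amp = tpl.amplitude_uV.get(ch, 0.0)
            if base_amp == 0.0:
                continue
            for cond in np.unique(conditions):
                idx = np.nonzero(conditions == cond)[0]
                amp = base_amp * tpl.scale(group, str(cond), ch)
                centers = tpl.mean_latency(group, str(cond), ch) + jitter[idx]
                # evaluate only over the bumps' joint support (±5 SD)
                margin = 5.0 * tpl.width_ms / _FWHM_TO_SD
                lo = np.searchsorted(t, centers.min() - margin)
                hi = np.searchsorted(t, centers.max() + margin)
                if lo >= hi:
                    continue
                out[np.ix_(idx, [ci], np.arange(lo, hi))] += (
                    amp * _gauss(t[None, lo:hi], centers[:, None], tpl.width_ms)
                )[:, None, :]
    return out


def simulate_participant_epochs(
    trials: list[TrialRecord],
    templates: list[ComponentTemplate] | None = None,
    noise: NoiseModel | None = None,
    trigger: str = "S",
    group: str = "controls",
    fs: float = 1024.0,
    seed: int | np.random.SeedSequence = 0,
    participant: int = 0,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
) -> EpochSet:
    """Direct epoch-stack generation (bypasses continuous synthesis).

    One epoch per trial around the requested trigger: planted components
    plus noise, ready for the baseline/reject/average stages.  Much faster
    than synthesising and re-epoching a continuous recording, and
    statistically equivalent for non-overlapping trials.
    """
    if templates is None:
        templates = default_templates()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    conditions = np.array([t.condition for t in trials], dtype=object)
    n_samp = window_samples(fs, window_ms)
    data = _evoked_epochs(
        conditions, templates, trigger, group, rng, CHANNELS, n_samp, fs, window_ms
    )
    data += _noise_block(noise, rng, len(trials), CHANNELS, n_samp, fs)
    return EpochSet(
        data=data,
        fs=fs,
        trigger=trigger,
        conditions=conditions,
        ch_names=CHANNELS,
        window_ms=window_ms,
        participant=participant,
        group=group,
    )


def synthesize_recording(
    trials: list[TrialRecord],
    templates: list[ComponentTemplate] | None = None,
    noise: NoiseModel | None = None,
    fs: float = 1024.0,
    seed: int | np.random.SeedSequence = 0,
    group: str = "controls",
    pad_s: float = 2.0,
) -> Recording:
    """Continuous EEG for a whole session with S/I event annotations.

    The signal is the sum of every trial's S- and I-locked component
    kernels placed on the session clock, plus continuous background noise
    and artifacts.  Trials whose S-I interval is shorter than 500 ms
    produce overlapping epochs; they are rendered anyway with a warning.
    """
    if templates is None:
        templates = default_templates()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    t_end = max(t.t_I for t in trials) + (EPOCH_WINDOW_MS[1] / 1000.0) + pad_s
    n_total = int(np.ceil((t_end + pad_s) * fs))
    events: list[Event] = []
    for tr in trials:
        if tr.t_I - tr.t_S < 0.5:
            warnings.warn(
                f"trial {tr.trial_index}: S-I interval {tr.t_I - tr.t_S:.3f}s < 0.5s; "
                "epochs will overlap",
                stacklevel=2,
            )
        events.append(Event(tr.t_S + pad_s, "S", tr.condition))
        events.append(Event(tr.t_I + pad_s, "I", tr.condition))

    data = np.zeros((len(CHANNELS), n_total))
    n_samp = window_samples(fs, EPOCH_WINDOW_MS)
    pre = round(-EPOCH_WINDOW_MS[0] / 1000.0 * fs)
    for trigger in ("S", "I"):
        evs = [e for e in events if e.trigger == trigger]
        conds = np.array([e.condition for e in evs], dtype=object)
        kernels = _evoked_epochs(
            conds, templates, trigger, group, rng, CHANNELS, n_samp, fs, EPOCH_WINDOW_MS
        )
        for k, ev in enumerate(evs):
            start = round(ev.onset_s * fs) - pre
            data[:, start : start + n_samp] += kernels[k]

    # Continuous background: one long "epoch" so artifact rates stay per-minute.
    data += _noise_block(noise, rng, 1, CHANNELS, n_total, fs)[0]
    return Recording(data=data, fs=fs, ch_names=CHANNELS, events=events)


# ---------------------------------------------------------------------------
# Recording I/O: raw float32 matrix + JSON sidecar, or minimal EDF+.

def write_recording(recording: Recording, path, format: str = "matrix") -> list:
    """Write a recording to ``path`` (base name without extension).

    ``matrix``: little-endian float32 raw matrix (row = channel) in
    ``<path>.bin``, sidecar ``<path>.json`` (fs, channels, events, dtype)
    and ``<path>.events.tsv``.  ``edf``: 16-bit EDF+ with an annotations
    channel carrying the events; samples are quantised to the physical
    range of the data.
    """
    from pathlib import Path

    base = Path(path)
    if format == "matrix":
        return _write_matrix(recording, base)
    if format == "edf":
        from . import edfwrite

        out = base.with_suffix(".edf")
        edfwrite.write_edf(recording, out)
        return [out]
    raise ValueError(f"unsupported format {format!r}")


def _write_matrix(recording: Recording, base) -> list:
    import json

    bin_path = base.with_suffix(".bin")
    json_path = base.with_suffix(".json")
    tsv_path = base.with_suffix(".events.tsv")
    recording.data.astype("<f4").tofile(bin_path)
    sidecar = {
        "fs": recording.fs,
        "channels": list(recording.ch_names),
        "n_samples": int(recording.n_samples),
        "dtype": "<f4",
        "order": "C",
        "unit": "uV",
        "events": [
            {"onset_s": e.onset_s, "trigger": e.trigger, "condition": e.condition}
            for e in recording.events
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    with open(tsv_path, "w") as fh:
        fh.write("onset_s\ttrigger\tcondition\n")
        for e in recording.events:
            fh.write(f"{e.onset_s:.6f}\t{e.trigger}\t{e.condition}\n")
    return [bin_path, json_path, tsv_path]


def read_recording(path, format: str = "matrix") -> Recording:
    """Read back a recording written by :func:`write_recording`."""
    import json
    from pathlib import Path

    base = Path(path)
    if format == "matrix":
        sidecar = json.loads(base.with_suffix(".json").read_text())
        data = np.fromfile(base.with_suffix(".bin"), dtype=sidecar["dtype"]).astype(float)
        data = data.reshape(len(sidecar["channels"]), sidecar["n_samples"])
        events = [
            Event(e["onset_s"], e["trigger"], e["condition"]) for e in sidecar["events"]
        ]
        return Recording(
            data=data,
            fs=sidecar["fs"],
            ch_names=tuple(sidecar["channels"]),
            events=events,
        )
    if format == "edf":
        from . import edfwrite

        return edfwrite.read_edf(base.with_suffix(".edf"))
    raise ValueError(f"unsupported format {format!r}")
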