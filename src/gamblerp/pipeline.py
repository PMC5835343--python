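"""ERP preprocessing chain: filter -> epoch -> baseline -> reject -> average.

Continuous EEG is band-passed 0.1–30 Hz (2-pole Butterworth, applied
forward-backward so latencies are not skewed), cut into 1,500 ms epochs
from −500 to +1,000 ms around the S (trial onset) and I (gamble choice)
triggers, baseline-corrected to the 500 ms pre-trigger interval, screened
for artifacts by peak-to-peak and gradient thresholds, and averaged per
feedback condition.  A participant/condition average is only produced when
more than twenty clean epochs remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "CHANNELS",
    "FRONTOCENTRAL",
    "CENTROPARIETAL",
    "EPOCH_WINDOW_MS",
    "Recording",
    "Event",
    "EpochSet",
    "ERPWaveform",
    "EpochCountError",
    "bandpass",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
    "average",
    "save_epochs",
    "load_epochs",
    "save_erp",
    "load_erp",
]

#: Midline 10/20 subset analysed throughout, frontal to posterior.
CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz", "POz")
FRONTOCENTRAL = ("Fz", "FCz", "Cz")
CENTROPARIETAL = ("CPz", "Pz", "POz")

#: Epoch window around each trigger, ms, half-open [lo, hi).
EPOCH_WINDOW_MS = (-500.0, 1000.0)


class EpochCountError(ValueError):
    """Raised when a condition average would rest on too few clean epochs."""


@dataclass(frozen=True)
class Event:
    onset_s: float
    trigger: str  # "S" or "I"
    condition: str  # "HF" or "LF"


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with annotated events."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    ch_names: tuple[str, ...]
    events: list[Event] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def window_samples(fs: float, window_ms: tuple[float, float] = EPOCH_WINDOW_MS) -> int:
    return round((window_ms[1] - window_ms[0]) / 1000.0 * fs)


@dataclass
class EpochSet:
    """Fixed-length epochs around one trigger type.

    ``data`` is (n_epochs, n_channels, n_samples) in microvolts with the
    trigger at time zero of the half-open window; ``rejected[i]`` is None
    for clean epochs or the name of the violated rule.
    """

    data: np.ndarray
    fs: float
    trigger: str
    conditions: np.ndarray  # str per epoch
    ch_names: tuple[str, ...] = CHANNELS
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS
    rejected: list[str | None] = field(default_factory=list)
    participant: int = 0
    group: str = "controls"

    def __post_init__(self) -> None:
        if not self.rejected:
            self.rejected = [None] * len(self.data)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs

    def retained_mask(self, condition: str | None = None) -> np.ndarray:
        mask = np.array([r is None for r in self.rejected])
        if condition is not None:
            mask &= self.conditions == condition
        return mask


@dataclass
class ERPWaveform:
    """Per-participant, per-condition average: channel x time, microvolts."""

    mean: np.ndarray
    n_epochs: int
    fs: float
    trigger: str
    condition: str
    participant: int = 0
    group: str = "controls"
    ch_names: tuple[str, ...] = CHANNELS
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(self.mean.shape[1]) * 1000.0 / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.mean[self.ch_names.index(name)]


def bandpass(recording: Recording, low: float = 0.1, high: float = 30.0) -> Recording:
    """Zero-phase 2-pole Butterworth band-pass (nominal −12 dB/octave).

    Applied forward and backward (``sosfiltfilt``) so component latencies
    are preserved; the effective roll-off consequently doubles.  DC is
    removed by the high-pass edge.
    """
    if recording.fs <= 2 * high:
        raise ValueError(f"fs={recording.fs} too low for high edge {high} Hz")
    sos = signal.butter(2, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    # pad well beyond the high-pass time constant (~1/(2π·low) s) so edge
    # transients from the 0.1 Hz pole do not leak into the recording
    padlen = int(min(recording.n_samples - 1, 5.0 / low * recording.fs))
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1, padlen=padlen)
    return replace(recording, data=filtered)


def epoch(
    recording: Recording,
    trigger: str,
    events: list[Event] | None = None,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    participant: int = 0,
    group: str = "controls",
) -> EpochSet:
    """Cut one epoch per matching event; trigger sample at t = 0.

    Events whose window would cross a recording edge are skipped with a
    warning.
    """
    if events is None:
        events = recording.events
    n_samp = window_samples(recording.fs, window_ms)
    pre = round(-window_ms[0] / 1000.0 * recording.fs)
    chunks, conds = [], []
    for ev in events:
        if ev.trigger != trigger:
            continue
        t0 = round(ev.onset_s * recording.fs)
        start = t0 - pre
        if start < 0 or start + n_samp > recording.n_samples:
            warnings.warn(
                f"event at {ev.onset_s:.3f}s too close to recording edge; skipped",
                stacklevel=2,
            )
            continue
        chunks.append(recording.data[:, start : start + n_samp])
        conds.append(ev.condition)
    data = (
        np.stack(chunks)
        if chunks
        else np.empty((0, len(recording.ch_names), n_samp))
    )
    return EpochSet(
        data=data,
        fs=recording.fs,
        trigger=trigger,
        conditions=np.array(conds, dtype=object),
        ch_names=tuple(recording.ch_names),
        window_ms=window_ms,
        participant=participant,
        group=group,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean of the pre-trigger interval."""
    if epochs.window_ms[0] >= 0:
        raise ValueError("epoch window has no pre-trigger baseline interval")
    base = epochs.times_ms < 0.0
    if epochs.n_epochs == 0:
        return epochs
    corrected = epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True)
    return replace(epochs, data=corrected, rejected=list(epochs.rejected))


def reject_artifacts(
    epochs: EpochSet,
    p2p_max_uV: float = 100.0,
    grad_max_uV_per_ms: float = 50.0,
) -> EpochSet:
    """Flag epochs exceeding peak-to-peak or sample-to-sample gradient limits.

    Automated stand-in for interactive artifact screening: blinks and large
    drifts trip the 100 µV peak-to-peak rule, muscle bursts the 50 µV/ms
    gradient rule.  Flags record the violated rule and stack onto any
    pre-existing flags.
    """
    flags = list(epochs.rejected)
    if epochs.n_epochs:
        p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (epochs, ch)
        grad = np.abs(np.diff(epochs.data, axis=2)) * epochs.fs / 1000.0
        bad_p2p = (p2p > p2p_max_uV).any(axis=1)
        bad_grad = (grad > grad_max_uV_per_ms).any(axis=(1, 2))
        for i in range(epochs.n_epochs):
            if flags[i] is None:
                if bad_p2p[i]:
                    flags[i] = "p2p"
                elif bad_grad[i]:
                    flags[i] = "gradient"
    return replace(epochs, rejected=flags)


MIN_EPOCHS = 20  # strictly more than this many clean epochs required


def average(epochs: EpochSet, condition: str) -> ERPWaveform:
    """Pointwise mean over retained epochs of one feedback condition.

    Refuses to average when twenty or fewer clean epochs remain, naming the
    participant and condition in the error.
    """
    mask = epochs.retained_mask(condition)
    n = int(mask.sum())
    if n <= MIN_EPOCHS:
        raise EpochCountError(
            f"participant {epochs.participant}, condition {condition}, trigger "
            f"{epochs.trigger}: only {n} usable epochs (> {MIN_EPOCHS} required)"
        )
    return ERPWaveform(
        mean=epochs.data[mask].mean(axis=0),
        n_epochs=n,
        fs=epochs.fs,
        trigger=epochs.trigger,
        condition=condition,
        participant=epochs.participant,
        group=epochs.group,
        ch_names=epochs.ch_names,
        window_ms=epochs.window_ms,
    )


# ---------------------------------------------------------------------------
# Persistence: matrix (.bin, little-endian float32) + JSON sidecar bundles.

def _write_bundle(data: np.ndarray, meta: dict, base) -> None:
    import json
    from pathlib import Path

    base = Path(base)
    data.astype("<f4").tofile(base.with_suffix(".bin"))
    meta = {**meta, "shape": list(data.shape), "dtype": "<f4", "order": "C"}
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _read_bundle(base):
    import json
    from pathlib import Path

    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    data = np.fromfile(base.with_suffix(".bin"), dtype=meta["dtype"]).astype(float)
    return data.reshape(meta["shape"]), meta


def save_epochs(epochs: EpochSet, base) -> None:
    """Write an EpochSet as a .bin matrix + .json sidecar bundle."""
    _write_bundle(
        epochs.data,
        {
            "kind": "epochs",
            "fs": epochs.fs,
            "trigger": epochs.trigger,
            "conditions": list(map(str, epochs.conditions)),
            "channels": list(epochs.ch_names),
            "window_ms": list(epochs.window_ms),
            "rejected": epochs.rejected,
            "participant": epochs.participant,
            "group": epochs.group,
        },
        base,
    )


def load_epochs(base) -> EpochSet:
    data, m = _read_bundle(base)
    return EpochSet(
        data=data,
        fs=m["fs"],
        trigger=m["trigger"],
        conditions=np.array(m["conditions"], dtype=object),
        ch_names=tuple(m["channels"]),
        window_ms=tuple(m["window_ms"]),
        rejected=m["rejected"],
        participant=m["participant"],
        group=m["group"],
    )


def save_erp(erp: ERPWaveform, base) -> None:
    """Write an ERPWaveform as a .bin matrix + .json sidecar bundle."""
    _write_bundle(
        erp.mean,
        {
            "kind": "erp",
            "fs": erp.fs,
            "trigger": erp.trigger,
            "condition": erp.condition,
            "n_epochs": erp.n_epochs,
            "channels": list(erp.ch_names),
            "window_ms": list(erp.window_ms),
            "participant": erp.participant,
            "group": erp.group,
        },
        base,
    )


def load_erp(base) -> ERPWaveform:
    data, m = _read_bundle(base)
    return ERPWaveform(
        mean=data,
        n_epochs=m["n_epochs"],
        fs=m["fs"],
        trigger=m["trigger"],
        condition=m["condition"],
        participant=m["participant"],
        group=m["group"],
        ch_names=tuple(m["channels"]),
        window_ms=tuple(m["window_ms"]),
    )
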