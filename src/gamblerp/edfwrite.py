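"""Minimal EDF+ (16-bit European Data Format) writer and reader.

Covers exactly what the synthetic recordings need: a continuous ("EDF+C")
file with one fixed sampling rate, microvolt signals quantised to a
symmetric physical range, and an "EDF Annotations" channel carrying the
S/I trigger events as time-stamped annotation lists (TALs) with
descriptions of the form ``"S/HF"``.  Data records last one second; the
final partial record is zero-padded, so readers should trust the sample
count in the JSON sidecar workflow or trim trailing padding themselves.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .pipeline import Event, Recording

__all__ = ["write_edf", "read_edf", "quantization_step_uV"]

_DIG_MAX = 32767


def quantization_step_uV(data: np.ndarray) -> float:
    """Physical value of one digital step for the range used by write_edf."""
    phys = max(float(np.max(np.abs(data))), 1.0)
    return phys / _DIG_MAX


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    if recording.fs != int(recording.fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(recording.fs)
    data = np.asarray(recording.data, dtype=float)
    n_ch, n_samples = data.shape
    if n_ch != len(recording.ch_names):
        raise ValueError("channel count does not match ch_names")
    n_records = math.ceil(n_samples / fs)

    phys_max = max(float(np.max(np.abs(data))) if data.size else 1.0, 1.0)
    scale = _DIG_MAX / phys_max
    padded = np.zeros((n_ch, n_records * fs), dtype="<i2")
    padded[:, :n_samples] = np.clip(np.rint(data * scale), -_DIG_MAX, _DIG_MAX).astype("<i2")

    # Annotation payload per record: timestamp TAL + the record's event TALs.
    tals = []
    for r in range(n_records):
        chunk = f"+{r}\x14\x14\x00"
        for ev in recording.events:
            if r <= ev.onset_s < r + 1:
                chunk += f"+{ev.onset_s:.6f}\x14{ev.trigger}/{ev.condition}\x14\x00"
        tals.append(chunk.encode("ascii"))
    ann_samples = max(60, math.ceil(max(len(t) for t in tals) / 2))

    ns = n_ch + 1
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("EDF+C", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )

    labels = list(recording.ch_names) + ["EDF Annotations"]
    dims = ["uV"] * n_ch + [""]
    pmins = [f"{-phys_max:.6g}"] * n_ch + ["-1"]
    pmaxs = [f"{phys_max:.6g}"] * n_ch + ["1"]
    dmins = [str(-_DIG_MAX)] * n_ch + ["-32768"]
    dmaxs = [str(_DIG_MAX)] * n_ch + ["32767"]
    spr = [str(fs)] * n_ch + [str(ann_samples)]
    sig_header = b"".join(
        b"".join(_ascii(v, w) for v in vals)
        for vals, w in (
            (labels, 16),
            ([""] * ns, 80),  # transducer
            (dims, 8),
            (pmins, 8),
            (pmaxs, 8),
            (dmins, 8),
            (dmaxs, 8),
            ([""] * ns, 80),  # prefiltering
            (spr, 8),
            ([""] * ns, 32),  # reserved
        )
    )

    with open(Path(path), "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            fh.write(padded[:, r * fs : (r + 1) * fs].tobytes())
            fh.write(tals[r].ljust(2 * ann_samples, b"\x00"))


def read_edf(path) -> Recording:
    raw = Path(path).read_bytes()

    def fld(off, width):
        return raw[off : off + width].decode("ascii").strip()

    n_records = int(fld(236, 8))
    ns = int(fld(252, 4))
    off = 256

    def sig(width):
        nonlocal off
        vals = [fld(off + i * width, width) for i in range(ns)]
        off += ns * width
        return vals

    labels = sig(16)
    sig(80)
    sig(8)  # transducer, dimension
    pmin = [float(v) for v in sig(8)]
    pmax = [float(v) for v in sig(8)]
    dmin = [int(v) for v in sig(8)]
    dmax = [int(v) for v in sig(8)]
    sig(80)
    spr = [int(v) for v in sig(8)]
    sig(32)

    ann_idx = labels.index("EDF Annotations") if "EDF Annotations" in labels else None
    data_off = 256 * (ns + 1)
    record_shorts = sum(spr)
    body = np.frombuffer(raw, dtype="<i2", offset=data_off)
    body = body[: n_records * record_shorts].reshape(n_records, record_shorts)

    starts = np.cumsum([0] + spr)
    channels, ch_names = [], []
    events: list[Event] = []
    for i in range(ns):
        chunk = body[:, starts[i] : starts[i + 1]]
        if i == ann_idx:
            for rec in chunk:
                for tal in rec.tobytes().split(b"\x00"):
                    if b"\x14" not in tal:
                        continue
                    onset_txt, *texts = tal.split(b"\x14")
                    for text in texts:
                        if b"/" in text:
                            trig, cond = text.decode("ascii").split("/")
                            events.append(Event(float(onset_txt), trig, cond))
            continue
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        channels.append((chunk.astype(float).ravel() - dmin[i]) * gain + pmin[i])
        ch_names.append(labels[i])
    fs = spr[0 if ann_idx != 0 else 1]  # record duration is 1 s
    return Recording(
        data=np.vstack(channels), fs=float(fs), ch_names=tuple(ch_names), events=events
    )
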