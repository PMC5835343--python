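"""Named ERP component peak detection and pooled latency tables.

A component peak is the largest polarity-signed local extremum strictly
inside the component's search window on a participant/condition average;
latencies are then pooled over the frontocentral (Fz, FCz, Cz) or
centroparietal (CPz, Pz, POz) electrodes by concatenating per-electrode
observations, mirroring how the study tabulates median and mean ± SEM
latencies per group and feedback condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import CENTROPARIETAL, FRONTOCENTRAL, ERPWaveform

__all__ = [
    "ComponentSpec",
    "ComponentPeak",
    "NoPeakError",
    "DEFAULT_SPECS",
    "detect_peak",
    "detect_component_peaks",
    "pooled_latency_table",
    "latency_summary",
    "check_component_ordering",
]

ROI_ELECTRODES = {
    "frontocentral": FRONTOCENTRAL,
    "centroparietal": CENTROPARIETAL,
}


class NoPeakError(ValueError):
    """No usable extremum (e.g. flat signal) in the search window."""


@dataclass(frozen=True)
class ComponentSpec:
    """Search recipe for one component on one trigger's epochs."""

    name: str
    polarity: int
    search_window_ms: tuple[float, float]
    applicable_trigger: str
    electrodes: tuple[str, ...] = FRONTOCENTRAL + CENTROPARIETAL

    def __post_init__(self) -> None:
        lo, hi = self.search_window_ms
        if lo >= hi:
            raise ValueError("search window must satisfy lo < hi")


#: Windows bracket the reported approximate latencies (N2 ~175 ms,
#: P3a ~250 ms, P3b ~340 ms, C1 ~70 ms posterior-only) with margins that
#: cover every tabulated group/condition median.
DEFAULT_SPECS = {
    "N2": ComponentSpec("N2", -1, (130.0, 230.0), "S"),
    "P3a": ComponentSpec("P3a", +1, (200.0, 310.0), "S"),
    "P3b": ComponentSpec("P3b", +1, (300.0, 430.0), "S"),
    "C1": ComponentSpec("C1", +1, (50.0, 110.0), "S", electrodes=("Pz", "POz")),
}


def specs_for_trigger(trigger: str) -> dict[str, ComponentSpec]:
    """Default component specs re-targeted to one trigger (C1 is S-only)."""
    out = {}
    for name, spec in DEFAULT_SPECS.items():
        if name == "C1" and trigger != "S":
            continue
        out[name] = ComponentSpec(
            spec.name, spec.polarity, spec.search_window_ms, trigger, spec.electrodes
        )
    return out


@dataclass(frozen=True)
class ComponentPeak:
    component: str
    electrode: str
    latency_ms: float
    amplitude_uV: float
    participant: int
    group: str
    condition: str
    trigger: str
    boundary: bool = False


def detect_peak(erp: ERPWaveform, spec: ComponentSpec, electrode: str) -> ComponentPeak:
    """Locate the component's extremum on one electrode of one average.

    The peak is the maximum of the polarity-signed waveform among local
    extrema strictly inside the window (ties break to the earliest); if
    the window contains no interior local extremum — e.g. a monotone ramp
    — the window extremum is returned flagged ``boundary``.
    """
    if electrode not in spec.electrodes:
        raise ValueError(f"{electrode} not among {spec.name} electrodes")
    if erp.trigger != spec.applicable_trigger:
        raise ValueError(
            f"{spec.name} targets trigger {spec.applicable_trigger}, got {erp.trigger}"
        )
    times = erp.times_ms
    lo, hi = spec.search_window_ms
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        raise NoPeakError("search window outside the epoch time base")
    y = spec.polarity * erp.channel(electrode)[sel]
    t = times[sel]
    if np.ptp(y) == 0:
        raise NoPeakError(f"flat signal in {spec.name} window at {electrode}")

    interior = np.zeros(len(y), dtype=bool)
    interior[1:-1] = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]) & (
        (y[1:-1] > y[:-2]) | (y[1:-1] > y[2:])
    )
    candidates = np.nonzero(interior)[0]
    boundary = False
    if len(candidates):
        best = candidates[np.argmax(y[candidates])]
        # earliest among exact ties
        ties = candidates[y[candidates] == y[best]]
        best = int(ties.min())
    else:
        best = int(np.argmax(y))
        boundary = True
    return ComponentPeak(
        component=spec.name,
        electrode=electrode,
        latency_ms=float(t[best]),
        amplitude_uV=float(erp.channel(electrode)[sel][best]),
        participant=erp.participant,
        group=erp.group,
        condition=erp.condition,
        trigger=erp.trigger,
        boundary=boundary,
    )


def detect_component_peaks(
    erps: list[ERPWaveform],
    specs: dict[str, ComponentSpec] | None = None,
) -> list[ComponentPeak]:
    """All (component, electrode) peaks across a set of averages."""
    peaks = []
    for erp in erps:
        use = specs if specs is not None else specs_for_trigger(erp.trigger)
        for spec in use.values():
            if spec.applicable_trigger != erp.trigger:
                continue
            for el in spec.electrodes:
                if el in erp.ch_names:
                    peaks.append(detect_peak(erp, spec, el))
    return peaks


def pooled_latency_table(peaks: list[ComponentPeak], roi: str) -> pd.DataFrame:
    """Long-format latency observations for one ROI.

    Pooling concatenates the per-electrode observations of the ROI's
    electrodes (no waveform averaging), so each participant contributes
    one row per electrode per component and condition.
    """
    electrodes = set(ROI_ELECTRODES[roi])
    rows = [
        {
            "participant": p.participant,
            "group": p.group,
            "condition": p.condition,
            "trigger": p.trigger,
            "component": p.component,
            "roi": roi,
            "electrode": p.electrode,
            "latency_ms": p.latency_ms,
            "amplitude_uV": p.amplitude_uV,
            "boundary": p.boundary,
        }
        for p in peaks
        if p.electrode in electrodes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "group", "condition", "trigger", "component",
            "roi", "electrode", "latency_ms", "amplitude_uV", "boundary",
        ],
    )


def latency_summary(observations: pd.DataFrame) -> pd.DataFrame:
    """Median and mean ± SEM per (trigger, component, roi, group, condition)."""
    if observations.empty:
        return pd.DataFrame()
    g = observations.groupby(["trigger", "component", "roi", "group", "condition"])
    out = g["latency_ms"].agg(
        median="median",
        mean="mean",
        sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
        n="size",
    )
    return out.reset_index()


def check_component_ordering(peaks: list[ComponentPeak]) -> list[str]:
    """Flag waveforms whose detected N2/P3a/P3b latencies are out of order."""
    flags = []
    df = pooled_latency_table(peaks, "frontocentral")
    df = pd.concat([df, pooled_latency_table(peaks, "centroparietal")])
    keys = ["participant", "group", "condition", "trigger", "electrode"]
    for key, sub in df.groupby(keys):
        lat = dict(zip(sub["component"], sub["latency_ms"]))
        if {"N2", "P3a", "P3b"} <= set(lat):
            if not (lat["N2"] < lat["P3a"] < lat["P3b"]):
                flags.append(
                    "ordering N2<P3a<P3b violated at "
                    + ", ".join(f"{k}={v}" for k, v in zip(keys, key))
                )
    return flags
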