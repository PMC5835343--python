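"""End-to-end synthetic study runs: behaviour -> EEG -> ERP tables -> reports.

Drives the full pipeline for a simulated cohort (default: the study's
effective EEG samples, controls and ADHD) and emits the tidy tables a
report needs: behavioural summaries (total gains, risk indexes, filtered
response times with group contrasts), component-latency observation and
summary tables, differential window-amplitude profiles, and a JSON
manifest with seeds, configuration and epoch bookkeeping.

Also hosts the parameter-recovery machinery used to validate the
generator/pipeline pair: plant component latencies, run the full
extraction, and compare pooled medians against the planted values.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .behavior import filter_rts, risk_index, session_summary
from .components import (
    detect_component_peaks,
    latency_summary,
    pooled_latency_table,
    specs_for_trigger,
)
from .differential import (
    I_WINDOW_CENTERS_MS,
    S_WINDOW_CENTERS_MS,
    DifferenceWave,
    difference_wave,
    profile_table,
    window_amplitude_profile,
)
from .pipeline import (
    ERPWaveform,
    average,
    baseline_correct,
    reject_artifacts,
)
from .simulate_eeg import (
    ComponentTemplate,
    NoiseModel,
    ROI_OF,
    default_templates,
    simulate_participant_epochs,
)
from .stats import mann_whitney, wilcoxon_signed
from .task import (
    TaskParams,
    adhd_profile,
    control_profile,
    simulate_session,
    trials_to_frame,
)

__all__ = [
    "StudyConfig",
    "simulate_participant_erps",
    "simulate_group_erps",
    "group_difference_waves",
    "planted_latencies",
    "latency_recovery_run",
    "add_frontal_interaction",
    "build_reports",
]


@dataclass(frozen=True)
class StudyConfig:
    """Cohort and generator settings for one synthetic study run."""

    n_controls: int = 18
    n_adhd: int = 14  # effective EEG sample after artifact-based exclusions
    fs: float = 1024.0
    params: TaskParams = field(default_factory=TaskParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    templates: list[ComponentTemplate] = field(default_factory=default_templates)
    triggers: tuple[str, ...] = ("S", "I")


_GROUP_CODE = {"controls": 0, "ADHD": 1}


def _profile_for(group: str):
    return control_profile() if group == "controls" else adhd_profile()


def _group_root(seed: int, group: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), _GROUP_CODE[group]])


def simulate_participant_erps(
    participant: int,
    group: str,
    seed_seq: np.random.SeedSequence,
    config: StudyConfig,
    trigger: str,
    trials=None,
) -> tuple[ERPWaveform, ERPWaveform, dict]:
    """One participant's (HF, LF) condition averages plus epoch bookkeeping."""
    beh_seq, eeg_seq = seed_seq.spawn(2)
    if trials is None:
        beh_seed = int(beh_seq.generate_state(1)[0] >> 1)
        trials = simulate_session(
            config.params, _profile_for(group), seed=beh_seed, participant_id=participant
        )
    epochs = simulate_participant_epochs(
        trials,
        templates=config.templates,
        noise=config.noise,
        trigger=trigger,
        group=group,
        fs=config.fs,
        seed=eeg_seq,
        participant=participant,
    )
    epochs = baseline_correct(epochs)
    epochs = reject_artifacts(epochs)
    counts = {
        "raw": epochs.n_epochs,
        "retained": int(epochs.retained_mask().sum()),
        "rejected_p2p": sum(r == "p2p" for r in epochs.rejected),
        "rejected_gradient": sum(r == "gradient" for r in epochs.rejected),
    }
    return average(epochs, "HF"), average(epochs, "LF"), counts


def simulate_group_erps(
    group: str,
    n: int,
    seed: int,
    config: StudyConfig,
    trigger: str,
    id_offset: int = 0,
) -> list[tuple[ERPWaveform, ERPWaveform]]:
    """(HF, LF) averages for ``n`` participants of one group."""
    root = _group_root(seed, group)
    out = []
    for i, child in enumerate(root.spawn(n)):
        erp_hf, erp_lf, _ = simulate_participant_erps(
            id_offset + i, group, child, config, trigger
        )
        out.append((erp_hf, erp_lf))
    return out


def group_difference_waves(
    erp_pairs: list[tuple[ERPWaveform, ERPWaveform]],
) -> list[DifferenceWave]:
    return [difference_wave(hf, lf) for hf, lf in erp_pairs]


def planted_latencies(
    templates: list[ComponentTemplate], trigger: str = "S"
) -> pd.DataFrame:
    """Generator ground truth: mean latency per (component, roi, group, condition)."""
    rows = []
    for tpl in templates:
        if tpl.trigger != trigger or tpl.name not in ("N2", "P3a", "P3b"):
            continue
        for group in ("controls", "ADHD"):
            for condition in ("HF", "LF"):
                for roi in ("frontocentral", "centroparietal"):
                    el = next(ch for ch, r in ROI_OF.items() if r == roi)
                    rows.append(
                        {
                            "trigger": trigger,
                            "component": tpl.name,
                            "roi": roi,
                            "group": group,
                            "condition": condition,
                            "planted_ms": tpl.mean_latency(group, condition, el),
                        }
                    )
    return pd.DataFrame(rows)


def latency_recovery_run(
    seed: int,
    n_per_group: int = 14,
    config: StudyConfig | None = None,
    trigger: str = "S",
    return_observations: bool = False,
):
    """Full generator->pipeline->peak-table run against planted truth.

    Returns the pooled latency summary merged with the generator's planted
    means and the recovery error per (component, roi, group, condition);
    with ``return_observations`` also the long observation table.
    """
    if config is None:
        config = StudyConfig()
    peaks = []
    for group in ("controls", "ADHD"):
        pairs = simulate_group_erps(group, n_per_group, seed, config, trigger)
        for erp_hf, erp_lf in pairs:
            peaks.extend(detect_component_peaks([erp_hf, erp_lf], specs_for_trigger(trigger)))
    obs = pd.concat(
        [
            pooled_latency_table(peaks, "frontocentral"),
            pooled_latency_table(peaks, "centroparietal"),
        ]
    )
    summary = latency_summary(obs[obs.component.isin(("N2", "P3a", "P3b"))])
    merged = summary.merge(
        planted_latencies(config.templates, trigger),
        on=["trigger", "component", "roi", "group", "condition"],
        how="left",
    )
    merged["error_ms"] = merged["median"] - merged["planted_ms"]
    if return_observations:
        return merged, obs
    return merged


def add_frontal_interaction(
    templates: list[ComponentTemplate],
    component: str = "P3a",
    trigger: str = "S",
    group: str = "ADHD",
    scale_hf: float = 1.4,
    scale_lf: float = 0.7,
) -> list[ComponentTemplate]:
    """Plant a frontocentral group-by-condition amplitude interaction.

    The named component's amplitude is scaled (HF up, LF down by default)
    for one group at the frontocentral sites only, so the group contrast
    of HF−LF difference waves becomes frontal and vanishes posteriorly.
    """
    out = []
    for tpl in templates:
        if tpl.name == component and tpl.trigger == trigger:
            scale = dict(tpl.amplitude_scale)
            scale[(group, "HF", "frontocentral")] = scale_hf
            scale[(group, "LF", "frontocentral")] = scale_lf
            tpl = replace(tpl, amplitude_scale=scale)
        out.append(tpl)
    return out


# ---------------------------------------------------------------------------
# Report bundle


def _behavior_rows(config: StudyConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_participant = []
    logs = []
    for group, n in (("controls", config.n_controls), ("ADHD", config.n_adhd)):
        for i in range(n):
            trials = simulate_session(
                config.params, _profile_for(group), seed=seed, participant_id=i
            )
            logs.append(trials_to_frame(trials).assign(group=group))
            retained, thr, out = filter_rts(trials)
            summ = session_summary(trials)
            row = {"participant": i, "group": group, "TotG": summ.TotG,
                   "TG_HF": summ.TG_HF, "TG_LF": summ.TG_LF,
                   "n_retained": summ.n_trials_retained,
                   "n_discarded_threshold": summ.n_discarded_threshold,
                   "n_discarded_outlier": summ.n_discarded_outlier}
            for cond in ("HF", "LF"):
                row[f"RI_{cond}"] = risk_index(retained, cond).RI
                rts = [t.rt_ms for t in retained if t.condition == cond]
                row[f"RT_{cond}_median"] = float(np.median(rts))
            per_participant.append(row)
    return pd.DataFrame(per_participant), pd.concat(logs, ignore_index=True)


def _behavior_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Group medians / means ± SEM with between-group U tests, one row per endpoint."""
    rows = []
    endpoints = ["TG_HF", "TG_LF", "RI_HF", "RI_LF", "RT_HF_median", "RT_LF_median", "TotG"]
    for ep in endpoints:
        a = df.loc[df.group == "controls", ep].to_numpy()
        b = df.loc[df.group == "ADHD", ep].to_numpy()
        res = mann_whitney(a, b)
        rows.append(
            {
                "endpoint": ep,
                "controls_median": np.median(a),
                "controls_mean": a.mean(),
                "controls_sem": a.std(ddof=1) / np.sqrt(len(a)),
                "adhd_median": np.median(b),
                "adhd_mean": b.mean(),
                "adhd_sem": b.std(ddof=1) / np.sqrt(len(b)),
                "U": res.statistic,
                "p": res.p_value,
                "r": res.effect_size,
            }
        )
    # within-group HF vs LF contrasts
    for group in ("controls", "ADHD"):
        sub = df[df.group == group]
        for pair, label in (
            (("TG_HF", "TG_LF"), "TG"),
            (("RI_HF", "RI_LF"), "RI"),
            (("RT_HF_median", "RT_LF_median"), "RT"),
        ):
            res = wilcoxon_signed(sub[pair[0]].to_numpy() - sub[pair[1]].to_numpy())
            rows.append(
                {
                    "endpoint": f"{label}_HFvsLF_{group}",
                    "Z": res.z,
                    "p": res.p_value,
                    "r": res.effect_size,
                }
            )
    return pd.DataFrame(rows)


def build_reports(out_dir, seed: int, config: StudyConfig | None = None) -> dict:
    """Run the whole synthetic study and write the report bundle.

    Writes trial logs, behaviour summaries, latency observations and
    summaries, differential window-amplitude profiles, and
    ``manifest.json`` (config, seed, versions, per-participant epoch
    bookkeeping) under ``out_dir``.  Same seed and config -> identical
    bundle.  Returns the manifest dict.
    """
    from pathlib import Path

    if config is None:
        config = StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    behavior, logs = _behavior_rows(config, seed)
    logs.to_csv(out / "trial_logs.csv", index=False)
    behavior.to_csv(out / "behavior_per_participant.csv", index=False)
    _behavior_summary(behavior).to_csv(out / "behavior_summary.csv", index=False)

    epoch_book: dict[str, dict] = {}
    all_obs = []
    window_tables = []
    for trigger in config.triggers:
        peaks = []
        diffs_by_group: dict[str, list[DifferenceWave]] = {}
        for group, n in (("controls", config.n_controls), ("ADHD", config.n_adhd)):
            root = _group_root(seed, group)
            pairs = []
            for i, child in enumerate(root.spawn(n)):
                erp_hf, erp_lf, counts = simulate_participant_erps(
                    i, group, child, config, trigger
                )
                pairs.append((erp_hf, erp_lf))
                epoch_book.setdefault(f"{group}-{i}", {"raw": 0})[trigger] = counts
                epoch_book[f"{group}-{i}"]["raw"] += counts["raw"]
            peaks.extend(
                p
                for pair in pairs
                for p in detect_component_peaks(list(pair), specs_for_trigger(trigger))
            )
            diffs_by_group[group] = group_difference_waves(pairs)
        obs = pd.concat(
            [
                pooled_latency_table(peaks, "frontocentral"),
                pooled_latency_table(peaks, "centroparietal"),
            ]
        )
        all_obs.append(obs)
        centers = S_WINDOW_CENTERS_MS if trigger == "S" else I_WINDOW_CENTERS_MS
        for group, diffs in diffs_by_group.items():
            profiles = {
                name: window_amplitude_profile(diffs, c, seed=seed)
                for name, c in centers.items()
            }
            window_tables.append(
                profile_table(profiles).assign(group=group, trigger=trigger)
            )

    obs = pd.concat(all_obs, ignore_index=True)
    obs.to_csv(out / "latency_observations.csv", index=False)
    latency_summary(obs).to_csv(out / "latency_summary.csv", index=False)
    pd.concat(window_tables, ignore_index=True).to_csv(
        out / "window_amplitude_profiles.csv", index=False
    )

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": int(seed),
        "config": {
            "n_controls": config.n_controls,
            "n_adhd": config.n_adhd,
            "fs": config.fs,
            "triggers": list(config.triggers),
            "n_blocks": config.params.n_blocks,
            "trials_per_block": config.params.trials_per_block,
        },
        "epochs_per_participant": epoch_book,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
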