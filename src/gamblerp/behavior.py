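"""Behavioural endpoints of the gambling task.

Three summaries characterise a session: total gains (``TotG``, the points
held summed over trials, also split by feedback condition into ``TG(HF)``
and ``TG(LF)``), a risk index ``RI = (HR - LR)/(HR + LR)`` built from the
fractions of high-stake (12/16/20) and low-stake (0/4/8) trials, and
response times after a two-stage cleaning: hard thresholds (RT < 250 ms or
RT > 10 s discarded) followed by Local Outlier Factor screening on log RT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import LocalOutlierFactor

from .task import TrialRecord

__all__ = [
    "RT_MIN_MS",
    "RT_MAX_MS",
    "HIGH_RISK_GAMBLES",
    "LOW_RISK_GAMBLES",
    "RiskSummary",
    "SessionSummary",
    "UndefinedIndexError",
    "filter_rts",
    "risk_index",
    "session_summary",
]

RT_MIN_MS = 250.0
RT_MAX_MS = 10_000.0
HIGH_RISK_GAMBLES = frozenset({12, 16, 20})
LOW_RISK_GAMBLES = frozenset({0, 4, 8})


class UndefinedIndexError(ValueError):
    """Risk index requested over an empty trial scope."""


@dataclass(frozen=True)
class RiskSummary:
    HR: float
    LR: float
    RI: float
    scope: str
    n_trials: int


@dataclass(frozen=True)
class SessionSummary:
    TotG: int
    TG_HF: int
    TG_LF: int
    n_trials_retained: int
    n_discarded_threshold: int
    n_discarded_outlier: int


def filter_rts(
    trials: list[TrialRecord],
    lof_k: int | None = None,
    lof_threshold: float = 1.5,
) -> tuple[list[TrialRecord], list[TrialRecord], list[TrialRecord]]:
    """Partition trials into (retained, threshold-discarded, outlier-discarded).

    Hard limits first: RT < 250 ms or RT > 10 s.  Survivors are then scored
    by Local Outlier Factor on log RT with ``k = min(20, n - 1)`` neighbours
    by default; scores above ``lof_threshold`` are flagged as outliers.
    When too few trials survive for a meaningful density estimate (fewer
    than ``lof_k + 1`` when ``lof_k`` is given, fewer than 8 otherwise) the
    outlier stage is skipped with a warning.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    survivors, thresholded = [], []
    for t in trials:
        (thresholded if (t.rt_ms < RT_MIN_MS or t.rt_ms > RT_MAX_MS) else survivors).append(t)

    n = len(survivors)
    min_n = (lof_k + 1) if lof_k is not None else 8
    if n < min_n:
        if survivors:
            warnings.warn(
                f"only {n} trials survive the RT thresholds; outlier stage skipped",
                stacklevel=2,
            )
        return survivors, thresholded, []
    k = min(20, n - 1) if lof_k is None else lof_k

    log_rt = np.log([t.rt_ms for t in survivors]).reshape(-1, 1)
    lof = LocalOutlierFactor(n_neighbors=k)
    lof.fit(log_rt)
    scores = -lof.negative_outlier_factor_
    retained = [t for t, s in zip(survivors, scores) if s <= lof_threshold]
    outliers = [t for t, s in zip(survivors, scores) if s > lof_threshold]
    return retained, thresholded, outliers


def risk_index(trials: list[TrialRecord], scope: str = "all") -> RiskSummary:
    """Risk attitude over retained trials.

    ``HR``/``LR`` are the relative counts of high-stake (12, 16, 20) and
    low-stake (0, 4, 8) trials; ``RI = (HR - LR)/(HR + LR)`` lies in
    [-1, +1], -1 flagging a risk-averse and +1 a risk-seeking strategy.
    ``scope`` restricts the computation to one feedback condition.
    """
    if scope not in ("all", "HF", "LF"):
        raise ValueError("scope must be 'all', 'HF' or 'LF'")
    pool = [t for t in trials if scope == "all" or t.condition == scope]
    if not pool:
        raise UndefinedIndexError(f"no trials in scope {scope!r}")
    n = len(pool)
    hr = sum(t.gamble in HIGH_RISK_GAMBLES for t in pool) / n
    lr = sum(t.gamble in LOW_RISK_GAMBLES for t in pool) / n
    return RiskSummary(HR=hr, LR=lr, RI=(hr - lr) / (hr + lr), scope=scope, n_trials=n)


def session_summary(trials: list[TrialRecord], **filter_kwargs) -> SessionSummary:
    """Total gains overall and per condition, with RT-cleaning bookkeeping.

    Gains sum ``points_after`` over *all* trials — points are earned
    whether or not the trial's RT later survives cleaning — while the
    retained/discarded counts report what the RT filter would keep.
    """
    tot = sum(t.points_after for t in trials)
    tg_hf = sum(t.points_after for t in trials if t.condition == "HF")
    tg_lf = sum(t.points_after for t in trials if t.condition == "LF")
    retained, thresholded, outliers = filter_rts(trials, **filter_kwargs)
    return SessionSummary(
        TotG=tot,
        TG_HF=tg_hf,
        TG_LF=tg_lf,
        n_trials_retained=len(retained),
        n_discarded_threshold=len(thresholded),
        n_discarded_outlier=len(outliers),
    )
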