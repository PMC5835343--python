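"""Probabilistic gambling task (PGT) simulation.

The task is a modified Gneezy-Potters investment game.  At each trial the
agent holds a fresh endowment of 20 points and stakes one of six allowed
amounts (0, 4, 8, 12, 16, 20).  The stake is lost with probability 2/3 and
returned fourfold with probability 1/3, so the points held after the trial
are ``endowment - gamble`` on a loss and ``endowment - gamble +
4 * gamble`` on a win.  Trials run in 10 alternating blocks of 16 trials:
in high-frequency feedback blocks (HF) the outcome is displayed after
every trial, in low-frequency blocks (LF) it is withheld.

Two session-clock events bracket every trial: ``S`` (spacebar press, trial
onset) and ``I`` (mouse click on the chosen stake).  Their spacing is the
response time, which is drawn from a condition-specific log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TaskParams",
    "AgentProfile",
    "TrialRecord",
    "InvalidGambleError",
    "resolve_trial",
    "build_session_design",
    "simulate_session",
    "control_profile",
    "adhd_profile",
    "trials_to_frame",
    "write_trial_log",
    "read_trial_log",
]

CONDITIONS = ("HF", "LF")

#: Longest representable response time, ms.  The behavioural filter discards
#: anything above 10 s; the generator may exceed that (those trials are the
#: ones the filter is for) but is truncated at twice the discard limit.
RT_CEILING_MS = 2 * 10_000.0


class InvalidGambleError(ValueError):
    """Raised when a stake outside the allowed set is played."""


@dataclass(frozen=True)
class TaskParams:
    """Design constants of the gambling task.

    Defaults reproduce the published design: 20-point endowment, stakes
    {0, 4, 8, 12, 16, 20}, win probability 1/3 with a 4x multiplier, and
    10 alternating HF/LF blocks of 16 trials (80 trials per condition).
    """

    endowment: int = 20
    allowed_gambles: tuple[int, ...] = (0, 4, 8, 12, 16, 20)
    win_probability: float = 1.0 / 3.0
    win_multiplier: int = 4
    n_blocks: int = 10
    trials_per_block: int = 16
    first_block_condition: str = "HF"
    # Session-clock pacing, seconds.  HF trials end with a 4 s outcome
    # display; LF trials show only a brief "outcome determined" message.
    outcome_display_s: float = 4.0
    lf_message_s: float = 1.0
    inter_trial_gap_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.win_probability < 1.0:
            raise ValueError("win_probability must lie in (0, 1)")
        if self.endowment <= 0:
            raise ValueError("endowment must be positive")
        if any(g < 0 or g > self.endowment for g in self.allowed_gambles):
            raise ValueError("allowed gambles must lie within [0, endowment]")
        if self.first_block_condition not in CONDITIONS:
            raise ValueError("first_block_condition must be 'HF' or 'LF'")
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ValueError("n_blocks and trials_per_block must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class AgentProfile:
    """Stochastic policy of a simulated participant.

    ``gamble_weights`` maps condition -> probability vector over the allowed
    stakes; ``rt_median_ms``/``rt_sigma`` parameterise a log-normal response
    time per condition (the median equals ``exp(mu)``).  Default group
    profiles are built by :func:`control_profile` and :func:`adhd_profile`.
    """

    group: str = "controls"
    gamble_weights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {c: (1 / 6,) * 6 for c in CONDITIONS}
    )
    rt_median_ms: dict[str, float] = field(
        default_factory=lambda: {"HF": 1083.0, "LF": 1032.0}
    )
    rt_sigma: dict[str, float] = field(default_factory=lambda: {c: 0.45 for c in CONDITIONS})
    seed_offset: int = 0

    def __post_init__(self) -> None:
        for cond, w in self.gamble_weights.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"gamble_weights[{cond}] must sum to 1")
            if any(p < 0 for p in w):
                raise ValueError("gamble_weights must be non-negative")
        if any(m <= 0 for m in self.rt_median_ms.values()):
            raise ValueError("rt_median_ms must be positive")


def control_profile(**overrides) -> AgentProfile:
    """Default control-group agent: risk-neutral stakes, group-median RTs."""
    return replace(AgentProfile(), **overrides)


def adhd_profile(**overrides) -> AgentProfile:
    """Default ADHD-group agent.

    Response-time medians follow the group medians (HF 1,544 ms, LF
    1,274 ms — ADHD responses are slower overall and faster under LF than
    HF); stake preferences stay risk-neutral since group risk indexes did
    not differ reliably.
    """
    prof = AgentProfile(
        group="ADHD",
        rt_median_ms={"HF": 1544.0, "LF": 1274.0},
        rt_sigma={c: 0.5 for c in CONDITIONS},
        seed_offset=1,
    )
    return replace(prof, **overrides)


@dataclass(frozen=True)
class TrialRecord:
    """One played trial with behavioural outcome and session-clock events."""

    participant_id: int
    block_index: int
    trial_index: int
    condition: str
    gamble: int
    won: bool
    points_after: int
    rt_ms: float
    t_S: float
    t_I: float


def resolve_trial(params: TaskParams, gamble: int, won: bool) -> int:
    """Points held after one trial under the payoff rule.

    A loss forfeits the stake: ``endowment - gamble``.  A win returns the
    stake fourfold on top: ``endowment - gamble + multiplier * gamble``
    (e.g. staking 8 of 20 yields 12 on a loss and 44 on a win).
    """
    if gamble not in params.allowed_gambles:
        raise InvalidGambleError(
            f"gamble {gamble} not in allowed set {params.allowed_gambles}"
        )
    base = params.endowment - gamble
    if won:
        return base + params.win_multiplier * gamble
    return base


def build_session_design(params: TaskParams) -> list[tuple[int, str]]:
    """Ordered (block_index, condition) pairs, one per trial.

    Conditions strictly alternate by block starting with
    ``first_block_condition``; with an even number of blocks the two
    conditions get equal trial counts.
    """
    first = CONDITIONS.index(params.first_block_condition)
    design = []
    for b in range(params.n_blocks):
        cond = CONDITIONS[(first + b) % 2]
        design.extend((b, cond) for _ in range(params.trials_per_block))
    return design


def _participant_rng(seed: int, participant_id: int, seed_offset: int = 0) -> np.random.Generator:
    # One independent stream per participant so sessions are reproducible
    # regardless of simulation order.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(participant_id), int(seed_offset)])
    )


def simulate_session(
    params: TaskParams,
    profile: AgentProfile,
    seed: int,
    participant_id: int = 0,
) -> list[TrialRecord]:
    """Play one full session and return its trial log.

    Stakes are drawn from the profile's per-condition weights, outcomes
    are Bernoulli(win_probability), and response times are log-normal with
    the profile's condition-specific median and dispersion, truncated to
    (0, 20 s].  Identical (seed, participant_id) -> identical log.
    """
    rng = _participant_rng(seed, participant_id, profile.seed_offset)
    gambles = np.asarray(params.allowed_gambles)
    design = build_session_design(params)

    records: list[TrialRecord] = []
    clock = 0.0
    for i, (block, cond) in enumerate(design):
        gamble = int(rng.choice(gambles, p=np.asarray(profile.gamble_weights[cond])))
        won = bool(rng.random() < params.win_probability)
        mu = np.log(profile.rt_median_ms[cond])
        rt = float(np.exp(rng.normal(mu, profile.rt_sigma[cond])))
        rt = min(rt, RT_CEILING_MS)
        t_s = clock
        t_i = t_s + rt / 1000.0
        records.append(
            TrialRecord(
                participant_id=participant_id,
                block_index=block,
                trial_index=i,
                condition=cond,
                gamble=gamble,
                won=won,
                points_after=resolve_trial(params, gamble, won),
                rt_ms=rt,
                t_S=t_s,
                t_I=t_i,
            )
        )
        display = params.outcome_display_s if cond == "HF" else params.lf_message_s
        clock = t_i + display + params.inter_trial_gap_s
    return records


# ---------------------------------------------------------------------------
# Trial-log I/O (CSV, one row per trial, TrialRecord columns)

_LOG_COLUMNS = [
    "participant_id", "block_index", "trial_index", "condition",
    "gamble", "won", "points_after", "rt_ms", "t_S", "t_I",
]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in trials], columns=_LOG_COLUMNS)


def write_trial_log(trials: list[TrialRecord], path) -> None:
    # %.17g keeps the clock/RT floats exactly round-trippable
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.17g")


def read_trial_log(path) -> list[TrialRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        TrialRecord(
            participant_id=int(r.participant_id),
            block_index=int(r.block_index),
            trial_index=int(r.trial_index),
            condition=str(r.condition),
            gamble=int(r.gamble),
            won=bool(r.won),
            points_after=int(r.points_after),
            rt_ms=float(r.rt_ms),
            t_S=float(r.t_S),
            t_I=float(r.t_I),
        )
        for r in df.itertuples()
    ]
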