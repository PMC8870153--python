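"""Anticipated-response stop signal task (Slater-Hammel style) simulator.

The task: after a fixation screen the participant presses and holds a button;
1400 ms later a car starts moving for 1000 ms.  On **go** trials the button
must be released inside an anticipated window 700-800 ms after motion onset.
On randomly interspersed **stop** trials the car halts spontaneously at the
stop signal delay (SSD, 300-700 ms) and the button must be held until the end
of the trial.  The SSD starts each block at 500 ms and is staircased in 50 ms
steps (success -> later/harder, failure -> earlier/easier) so that the
probability of successful stopping converges to ~0.5.

Subjects are modelled as a horse race between an anticipatory go process
(planned release latency, motion-locked) and a stop process triggered by the
stop cue: the stop wins iff ``ssd + ssrt_i <= planned_release``.  The stop
signal reaction time (SSRT) is estimated with the "means" method,
``SSRT = mean(GO-RT) - mean(SSD)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import ceil, floor
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "SubjectModel",
    "TrialRecord",
    "BehavioralSummary",
    "GO",
    "STOP",
    "generate_schedule",
    "stop_counts",
    "classify_go_response",
    "resolve_stop_trial",
    "update_ssd",
    "run_session",
    "summarize_behavior",
    "ssrt_means_method",
    "trials_to_frame",
    "write_behavior_tsv",
]

GO = "go"
STOP = "stop"

#: outcome labels
GO_SUCCESS = "go_success"
GO_EARLY = "go_early"
GO_LATE = "go_late"
STOP_SUCCESS = "stop_success"
STOP_FAIL = "stop_fail"

FEEDBACK = {
    GO_SUCCESS: "Great job!",
    GO_EARLY: "Too early!",
    GO_LATE: "Too late!",
    STOP_SUCCESS: "Great job!",
    STOP_FAIL: "Too early!",
}


class ConfigurationError(ValueError):
    """Raised for invalid task / subject configurations."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing and structure of the task.  All durations in ms."""

    n_blocks: int = 4
    trials_per_block: int = 40
    ssd_initial: float = 500.0
    ssd_step: float = 50.0
    ssd_min: float = 300.0
    ssd_max: float = 700.0
    go_window: tuple[float, float] = (700.0, 800.0)
    motion_duration: float = 1000.0
    pre_motion_delay: float = 1400.0
    fixation_duration: float = 2000.0
    stop_hold_success: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("block/trial counts must be positive")
        if not (self.ssd_min <= self.ssd_initial <= self.ssd_max):
            raise ConfigurationError("need ssd_min <= ssd_initial <= ssd_max")
        lo, hi = self.go_window
        if not (0 < lo < hi <= self.motion_duration):
            raise ConfigurationError("go_window must lie inside (0, motion_duration]")
        for name in ("ssd_step", "motion_duration", "pre_motion_delay",
                     "fixation_duration", "stop_hold_success"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class SubjectModel:
    """Generative horse-race subject.

    ``go_mu``/``go_sigma`` parameterize the planned (anticipatory) release
    latency relative to motion onset; ``ssrt_mu``/``ssrt_sigma`` the latency
    of the internal stop process relative to the stop cue.  Both are
    truncated-normal (>0).  ``go_omission_rate`` is the probability that the
    button is never released on a go trial.
    """

    go_mu: float = 798.0
    go_sigma: float = 25.0
    ssrt_mu: float = 250.0
    ssrt_sigma: float = 35.0
    go_omission_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.go_sigma < 0 or self.ssrt_sigma < 0:
            raise ConfigurationError("sigmas must be >= 0")
        if not 0 <= self.go_omission_rate < 1:
            raise ConfigurationError("go_omission_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial.  Latencies are motion-locked, in ms."""

    phase: str  # "practice_go" | "practice_stop" | "practice_mixed" | "main"
    block: int
    trial: int
    trial_type: str  # "go" | "stop"
    ssd: float | None
    planned_release: float | None
    release_latency: float | None
    outcome: str
    feedback: str

    @property
    def is_main(self) -> bool:
        return self.phase == "main"


def stop_counts(cfg: TaskConfig) -> list[int]:
    """Stop-trial count per block realizing the 2:1 go:stop ratio.

    ``trials_per_block/3`` is generally not an integer; blocks alternate
    floor/ceil so the session total stays as close to the ratio as possible
    (4 x 40 -> 13,14,13,14 = 54 stop / 106 go).
    """
    exact = cfg.trials_per_block / 3
    lo, hi = floor(exact), ceil(exact)
    return [lo if b % 2 == 0 else hi for b in range(cfg.n_blocks)]


def generate_schedule(cfg: TaskConfig, seed: int) -> list[list[str]]:
    """Planned trial types per block, order randomized within block."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    blocks = []
    for b, n_stop in enumerate(stop_counts(cfg)):
        types = [STOP] * n_stop + [GO] * (cfg.trials_per_block - n_stop)
        order = rng.permutation(len(types))
        blocks.append([types[i] for i in order])
    return blocks


def classify_go_response(
    release_latency: float | None, cfg: TaskConfig
) -> tuple[str, str]:
    """Classify a go-trial button release against the anticipated window."""
    if release_latency is None:
        return GO_LATE, FEEDBACK[GO_LATE]
    if release_latency < 0:
        raise ValueError("release latency must be >= 0")
    lo, hi = cfg.go_window
    if release_latency < lo:
        return GO_EARLY, FEEDBACK[GO_EARLY]
    if release_latency <= hi:
        return GO_SUCCESS, FEEDBACK[GO_SUCCESS]
    return GO_LATE, FEEDBACK[GO_LATE]


def resolve_stop_trial(
    planned_release: float, ssrt_i: float, ssd: float, cfg: TaskConfig
) -> tuple[str, float | None]:
    """Horse race: the stop process wins iff it finishes before the planned
    release (``ssd + ssrt_i <= planned_release``).

    Returns ``(outcome, release_latency)``; the release latency is the
    planned one on failed stops and ``None`` (button held) on successful ones.
    """
    if not (cfg.ssd_min <= ssd <= cfg.ssd_max):
        raise ValueError(f"ssd {ssd} outside [{cfg.ssd_min}, {cfg.ssd_max}]")
    if ssd + ssrt_i <= planned_release:
        return STOP_SUCCESS, None
    return STOP_FAIL, planned_release


def update_ssd(current: float, stop_success: bool, cfg: TaskConfig) -> float:
    """One staircase step: success -> later cue (harder), failure -> earlier."""
    if not (cfg.ssd_min <= current <= cfg.ssd_max):
        raise ValueError(f"ssd {current} outside [{cfg.ssd_min}, {cfg.ssd_max}]")
    step = cfg.ssd_step if stop_success else -cfg.ssd_step
    return float(min(cfg.ssd_max, max(cfg.ssd_min, current + step)))


def _trunc_normal(rng: np.random.Generator, mu: float, sigma: float, n: int = 1) -> np.ndarray:
    """Normal truncated to (0, inf) by rejection; sigma=0 -> constant."""
    if sigma == 0:
        return np.full(n, float(mu))
    out = rng.normal(mu, sigma, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = out <= 0
    return out


def _run_block(
    phase: str,
    block: int,
    types: Sequence[str],
    cfg: TaskConfig,
    subject: SubjectModel,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    records = []
    ssd = cfg.ssd_initial  # staircase restarts every block
    for i, ttype in enumerate(types, start=1):
        planned = float(_trunc_normal(rng, subject.go_mu, subject.go_sigma)[0])
        if ttype == GO:
            omitted = subject.go_omission_rate > 0 and rng.random() < subject.go_omission_rate
            release = None if omitted else planned
            outcome, fb = classify_go_response(release, cfg)
            rec = TrialRecord(phase, block, i, GO, None, planned, release, outcome, fb)
        else:
            ssrt_i = float(_trunc_normal(rng, subject.ssrt_mu, subject.ssrt_sigma)[0])
            outcome, release = resolve_stop_trial(planned, ssrt_i, ssd, cfg)
            rec = TrialRecord(phase, block, i, STOP, ssd, planned, release,
                              outcome, FEEDBACK[outcome])
            ssd = update_ssd(ssd, outcome == STOP_SUCCESS, cfg)
        records.append(rec)
    return records


def run_session(
    cfg: TaskConfig,
    subject: SubjectModel,
    seed: int,
    include_practice: bool = True,
) -> list[TrialRecord]:
    """Simulate one full session: practice (10 go, 10 stop, 20 mixed; flagged,
    excluded from all summaries) followed by the main mixed blocks."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    schedule = generate_schedule(cfg, seed)
    records: list[TrialRecord] = []
    if include_practice:
        mixed_stop = max(1, round(20 / 3))
        mixed = [STOP] * mixed_stop + [GO] * (20 - mixed_stop)
        mixed = [mixed[i] for i in rng.permutation(len(mixed))]
        records += _run_block("practice_go", 0, [GO] * 10, cfg, subject, rng)
        records += _run_block("practice_stop", 0, [STOP] * 10, cfg, subject, rng)
        records += _run_block("practice_mixed", 0, mixed, cfg, subject, rng)
    for b, types in enumerate(schedule, start=1):
        records += _run_block("main", b, types, cfg, subject, rng)
    return records


def ssrt_means_method(go_rt_mean: float, ssd_mean: float) -> float:
    """Means-method SSRT: mean GO-RT minus mean SSD."""
    return go_rt_mean - ssd_mean


@dataclass
class BehavioralSummary:
    """Per-block and pooled behavioral measures.

    ``table`` is indexed by block (ints) plus ``"block_mean"`` (mean of the
    per-block rows) and ``"overall"`` (pooled across all main trials), with
    columns n_go, n_stop, p_inhibit, go_success_rate, go_rt_mean, ssd_mean,
    ssrt.  The identity ``ssrt == go_rt_mean - ssd_mean`` holds on every row.
    """

    table: pd.DataFrame

    @property
    def overall(self) -> pd.Series:
        return self.table.loc["overall"]


def _summarize(df: pd.DataFrame) -> dict:
    go = df[df.trial_type == GO]
    stop = df[df.trial_type == STOP]
    if go.empty or stop.empty:
        raise ValueError("need at least one go and one stop trial per summarized unit")
    go_rts = go.release_latency.dropna()
    if go_rts.empty:
        raise ValueError("no realized go releases; GO-RT undefined")
    go_rt_mean = float(go_rts.mean())
    ssd_mean = float(stop.ssd.mean())
    return {
        "n_go": len(go),
        "n_stop": len(stop),
        "p_inhibit": float((stop.outcome == STOP_SUCCESS).mean()),
        "go_success_rate": float((go.outcome == GO_SUCCESS).mean()),
        "go_rt_mean": go_rt_mean,
        "ssd_mean": ssd_mean,
        "ssrt": ssrt_means_method(go_rt_mean, ssd_mean),
    }


def summarize_behavior(trials: Iterable[TrialRecord]) -> BehavioralSummary:
    """Behavioral summary over the main trials (practice excluded).

    GO-RT averages only go trials with a realized release (omissions are
    classified go_late and excluded); failed-stop releases never enter GO-RT.
    """
    df = trials_to_frame(trials)
    df = df[df.phase == "main"]
    if df.empty:
        raise ValueError("no main trials to summarize")
    rows = {b: _summarize(g) for b, g in df.groupby("block")}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    block_mean = table.mean(axis=0)
    # the across-block mean must preserve the SSRT identity
    block_mean["ssrt"] = block_mean["go_rt_mean"] - block_mean["ssd_mean"]
    table.loc["block_mean"] = block_mean
    table.loc["overall"] = pd.Series(_summarize(df))
    return BehavioralSummary(table)


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in trials])


def write_behavior_tsv(
    trials: Iterable[TrialRecord], path, metadata: dict | None = None
) -> None:
    """Behavioral log: one row per trial, tab-separated, with commented
    session metadata (seed, config hash, ...) header lines."""
    df = trials_to_frame(trials)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
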