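"""Synthetic observers: experiment designs, scanpath simulation, fixation reports.

The simulator is a deliberately simple parametric stand-in for a human
searcher.  Each observer is described by :class:`ObserverParams`; the key
parameter ``w_het`` is the probability that each post-initial fixation is
directed at a heterogeneous (difficulty > 0.5) cell.  The mixture is
normalised within the heterogeneous/homogeneous cell classes so that, with
no upper-field bias and no amplitude penalty, the long-run fraction of
fixations on heterogeneous cells equals ``w_het`` exactly — the link that
the downstream parameter-recovery harness exploits.

Peripheral target detection is distance-based: detection radii interpolate
linearly between a large radius at difficulty 0 (ceiling detection on easy
backgrounds) and a small radius at difficulty 1 (chance in the periphery on
hard backgrounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stimgen import (
    DEFAULT_THETA,
    EXP1_GRID,
    EXP2_GRID,
    GridSpec,
    OrientationRangeMapping,
    StimulusArray,
    make_jumbled,
    make_split_half,
    make_uniform,
)

__all__ = [
    "REPORT_COLUMNS",
    "EXP1_TIMEOUT_MS",
    "PASSIVE_VIEW_MS",
    "ObserverParams",
    "PopulationSpec",
    "DesignSpec",
    "TrialRecord",
    "make_design",
    "stimulus_for_trial",
    "next_fixation",
    "peripheral_detect",
    "simulate_trial",
    "simulate_session",
    "sample_population",
    "records_to_frame",
    "frame_to_records",
    "write_fixation_report",
]

EXP1_TIMEOUT_MS = 60_000.0
PASSIVE_VIEW_MS = 5_000.0

#: Flat fixation-report schema: one row per fixation.
REPORT_COLUMNS = [
    "participant",
    "trial",
    "phase",
    "block",
    "condition",
    "configuration",
    "target_present",
    "target_half",
    "target_col",
    "target_row",
    "response",
    "correct",
    "rt_ms",
    "stim_seed",
    "fix_index",
    "x_px",
    "y_px",
    "dur_ms",
]


@dataclass(frozen=True)
class ObserverParams:
    """Parametric search strategy of one simulated participant.

    ``detect_radius_easy``/``detect_radius_hard`` are expressed in cells and
    interpolated by the difficulty of the target's cell.  ``giveup_fix`` is
    the fixation budget before responding "absent".  Passive-viewing biases
    default to the search-phase values when not set.
    """

    w_het: float = 0.5
    upper_bias: float = 1.0
    amp_scale: float = math.inf
    detect_radius_easy: float = 41.0
    detect_radius_hard: float = 0.75
    fix_dur_median_ms: float = 250.0
    fix_dur_sigma: float = 0.3
    giveup_fix: int = 12
    jitter_px: float = 4.0
    w_het_passive: float | None = None
    upper_bias_passive: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_het <= 1.0:
            raise ValueError("w_het must lie in [0, 1]")
        if self.upper_bias < 0:
            raise ValueError("upper_bias must be >= 0")
        if not (self.detect_radius_easy >= self.detect_radius_hard >= 0):
            raise ValueError("require detect_radius_easy >= detect_radius_hard >= 0")
        if self.giveup_fix < 1:
            raise ValueError("giveup_fix must be >= 1")
        if self.fix_dur_median_ms <= 0 or self.fix_dur_sigma < 0:
            raise ValueError("invalid fixation-duration parameters")


@dataclass(frozen=True)
class PopulationSpec:
    """Population distribution over :class:`ObserverParams`.

    ``w_het`` is drawn from Beta(a, b) unless ``w_het_fixed`` is given; all
    other parameters are copied from ``template``.
    """

    w_het_beta: tuple[float, float] = (2.0, 2.0)
    w_het_fixed: float | None = None
    template: ObserverParams = field(default_factory=ObserverParams)

    def __post_init__(self) -> None:
        a, b = self.w_het_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta hyperparameters must be positive")
        if self.w_het_fixed is not None and not 0 <= self.w_het_fixed <= 1:
            raise ValueError("w_het_fixed must lie in [0, 1]")


@dataclass(frozen=True)
class DesignSpec:
    experiment: str  # exp1 | exp2
    trials: pd.DataFrame  # columns: trial, phase, block, condition, configuration,
    #                       target_present, target_half


@dataclass
class TrialRecord:
    participant: str
    trial: int
    phase: str  # passive | practice | search
    block: int
    condition: str
    configuration: str
    target_present: bool
    target_half: str  # easy | hard | any | absent
    target_col: int | None
    target_row: int | None
    response: str  # present | absent | timeout | none
    correct: bool | None
    rt_ms: float
    stim_seed: int
    fixations: list[tuple[float, float, float]]  # (x_px, y_px, dur_ms)


def make_design(experiment: str, seed: int = 0) -> DesignSpec:
    """Randomised trial list for one session.

    exp1: 10 passive-viewing trials, 5 practice trials, then 160 search
    trials (40 target-on-easy-half, 40 target-on-hard-half, 80 target-absent,
    randomly intermixed in 4 blocks of 40) with the hard side assigned to
    the upper or lower half at random on every trial.

    exp2: 100 search trials in 4 blocks of 25; 25 trials per condition
    (easy, hard, split_half, jumbled) mixed within blocks, with target
    presence balanced at 50 trials overall (13/12 per condition).
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    if experiment == "exp1":
        configs = ("hard_up", "hard_down")
        for _ in range(10):
            rows.append(
                dict(phase="passive", block=0, condition="split_half",
                     configuration=str(rng.choice(configs)),
                     target_present=False, target_half="absent")
            )
        practice_halves = list(rng.permutation(["easy", "hard", "absent", "absent", "absent"]))
        for half in practice_halves:
            rows.append(
                dict(phase="practice", block=0, condition="split_half",
                     configuration=str(rng.choice(configs)),
                     target_present=half != "absent", target_half=half)
            )
        halves = ["easy"] * 40 + ["hard"] * 40 + ["absent"] * 80
        for i, half in enumerate(rng.permutation(halves)):
            rows.append(
                dict(phase="search", block=1 + i // 40, condition="split_half",
                     configuration=str(rng.choice(configs)),
                     target_present=half != "absent", target_half=str(half))
            )
    elif experiment == "exp2":
        conditions = ("easy", "hard", "split_half", "jumbled")
        present_counts = {"easy": 13, "hard": 12, "split_half": 13, "jumbled": 12}
        pool: list[dict] = []
        for cond in conditions:
            flags = [True] * present_counts[cond] + [False] * (25 - present_counts[cond])
            for present in flags:
                if cond == "split_half":
                    config = str(rng.choice(("hard_left", "hard_right")))
                    half = str(rng.choice(("easy", "hard"))) if present else "absent"
                else:
                    config = "none"
                    half = "any" if present else "absent"
                pool.append(
                    dict(phase="search", condition=cond, configuration=config,
                         target_present=present, target_half=half)
                )
        order = rng.permutation(len(pool))
        for i, j in enumerate(order):
            row = dict(pool[j])
            row["block"] = 1 + i // 25
            rows.append(row)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    frame = pd.DataFrame(rows)
    frame.insert(0, "trial", np.arange(len(frame)))
    return DesignSpec(experiment, frame)


def stimulus_for_trial(
    experiment: str,
    condition: str,
    configuration: str,
    target_present: bool,
    target_half: str,
    stim_seed: int,
    mapping: OrientationRangeMapping | None = None,
    theta: float = DEFAULT_THETA,
) -> StimulusArray:
    """Deterministically (re)build the stimulus for one trial row."""
    if condition == "split_half":
        grid = EXP1_GRID if experiment == "exp1" else EXP2_GRID
        axis = "horizontal" if configuration in ("hard_up", "hard_down") else "vertical"
        hard_side = configuration.removeprefix("hard_")
        half = target_half if target_present else "absent"
        return make_split_half(grid, axis, hard_side, half, mapping, stim_seed, theta)
    if condition in ("easy", "hard"):
        return make_uniform(condition, EXP2_GRID, target_present, mapping, stim_seed, theta)
    if condition == "jumbled":
        return make_jumbled(EXP2_GRID, mapping, target_present, stim_seed, theta)
    raise ValueError(f"unknown condition {condition!r}")


def _cell_centres(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    ox, oy = grid.origin_px
    xs = ox + (np.arange(grid.n_cols) + 0.5) * grid.cell_px
    ys = oy + (np.arange(grid.n_rows) + 0.5) * grid.cell_px
    return np.meshgrid(xs, ys)


def next_fixation(
    current_xy: tuple[float, float],
    stim: StimulusArray,
    params: ObserverParams,
    rng: np.random.Generator,
    w_het: float | None = None,
    upper_bias: float | None = None,
) -> tuple[float, float]:
    """Sample the next fixated cell and return its centre plus pixel jitter.

    Cell weights form a binary mixture over the heterogeneous/homogeneous
    cell classes (class-normalised so P(heterogeneous) = w_het when both
    classes are non-empty), multiplied by ``upper_bias`` for upper-half
    cells and by exp(-distance / amp_scale); the currently fixated cell is
    excluded.
    """
    if w_het is None:
        w_het = params.w_het
    if upper_bias is None:
        upper_bias = params.upper_bias
    grid = stim.grid
    het = stim.cell_difficulty > 0.5
    n_het = int(het.sum())
    n_homo = het.size - n_het
    if n_het and n_homo:
        weights = np.where(het, w_het / n_het, (1.0 - w_het) / n_homo)
    else:
        weights = np.full(het.shape, 1.0 / het.size)
    if upper_bias != 1.0:
        upper = np.broadcast_to(
            (np.arange(grid.n_rows) < grid.n_rows / 2)[:, None], het.shape
        )
        weights = np.where(upper, weights * upper_bias, weights)
    if math.isfinite(params.amp_scale):
        cx, cy = _cell_centres(grid)
        dist = np.hypot(cx - current_xy[0], cy - current_xy[1]) / grid.cell_px
        weights = weights * np.exp(-dist / params.amp_scale)
    cur = grid.cell_at(*current_xy)
    if cur is not None:
        weights = weights.copy()
        weights[cur[1], cur[0]] = 0.0
    total = weights.sum()
    if total <= 0:  # every candidate zeroed out: fall back to uniform
        weights = np.ones(het.shape)
        if cur is not None:
            weights[cur[1], cur[0]] = 0.0
        total = weights.sum()
    flat = weights.ravel() / total
    idx = rng.choice(flat.size, p=flat)
    row, col = np.unravel_index(idx, het.shape)
    x, y = grid.cell_centre(int(col), int(row))
    jx, jy = rng.uniform(-params.jitter_px, params.jitter_px, size=2)
    return (float(x + jx), float(y + jy))


def peripheral_detect(
    fix_xy: tuple[float, float],
    stim: StimulusArray,
    params: ObserverParams,
    rng: np.random.Generator | None = None,
) -> bool:
    """Whether the target is detected from the given fixation.

    The detection radius interpolates between the easy and hard radii by the
    target cell's difficulty; the distance is measured between cell indices
    (fixated cell vs target cell), so a radius of 0 detects only when the
    target's own cell is fixated.
    """
    if not stim.target.present or stim.target.cell is None:
        raise ValueError("peripheral_detect requires a present target")
    grid = stim.grid
    ox, oy = grid.origin_px
    col = int(np.clip((fix_xy[0] - ox) // grid.cell_px, 0, grid.n_cols - 1))
    row = int(np.clip((fix_xy[1] - oy) // grid.cell_px, 0, grid.n_rows - 1))
    tcol, trow = stim.target.cell
    d_target = float(stim.cell_difficulty[trow, tcol])
    radius = params.detect_radius_easy + d_target * (
        params.detect_radius_hard - params.detect_radius_easy
    )
    dist = math.hypot(col - tcol, row - trow)
    return dist <= radius


def simulate_trial(
    stim: StimulusArray,
    params: ObserverParams,
    rng: np.random.Generator,
    phase: str = "search",
    timeout_ms: float | None = None,
    passive_ms: float = PASSIVE_VIEW_MS,
) -> tuple[str, bool | None, float, list[tuple[float, float, float]]]:
    """Simulate one trial; returns (response, correct, rt_ms, fixations).

    Fixation 1 is at the array centre (trials start on the fixation cross).
    On search trials the observer responds "present" as soon as the target
    is peripherally detected, "absent" once the fixation budget is spent,
    or "timeout" when the elapsed time reaches ``timeout_ms``.  Passive
    trials simply accumulate fixations for ``passive_ms`` with no response.
    """
    mu = math.log(params.fix_dur_median_ms)
    fixations: list[tuple[float, float, float]] = []
    x, y = stim.grid.centre_px
    t = 0.0

    if phase == "passive":
        w = params.w_het_passive if params.w_het_passive is not None else params.w_het
        ub = params.upper_bias_passive if params.upper_bias_passive is not None else params.upper_bias
        while t < passive_ms:
            dur = float(rng.lognormal(mu, params.fix_dur_sigma))
            dur = min(dur, passive_ms - t)
            fixations.append((x, y, dur))
            t += dur
            if t < passive_ms:
                x, y = next_fixation((x, y), stim, params, rng, w_het=w, upper_bias=ub)
        return ("none", None, passive_ms, fixations)

    response = None
    n_fix = 0
    while response is None:
        dur = float(rng.lognormal(mu, params.fix_dur_sigma))
        if timeout_ms is not None and t + dur >= timeout_ms:
            fixations.append((x, y, timeout_ms - t))
            t = timeout_ms
            response = "timeout"
            break
        fixations.append((x, y, dur))
        t += dur
        n_fix += 1
        if stim.target.present and peripheral_detect((x, y), stim, params, rng):
            response = "present"
        elif n_fix >= params.giveup_fix:
            response = "absent"
        else:
            x, y = next_fixation((x, y), stim, params, rng)
    correct = (response == "present") == stim.target.present if response != "timeout" else False
    return (response, correct, t, fixations)


def simulate_session(
    participant: str,
    design: DesignSpec,
    params: ObserverParams,
    seed: int | None = None,
    mapping: OrientationRangeMapping | None = None,
) -> list[TrialRecord]:
    """Simulate a full session for one participant against a trial design."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    timeout = EXP1_TIMEOUT_MS if design.experiment == "exp1" else None
    records: list[TrialRecord] = []
    for row in design.trials.itertuples(index=False):
        stim_seed = int(rng.integers(0, 2**31 - 1))
        stim = stimulus_for_trial(
            design.experiment, row.condition, row.configuration,
            row.target_present, row.target_half, stim_seed, mapping,
        )
        trial_timeout = timeout if row.phase != "passive" else None
        response, correct, rt, fixations = simulate_trial(
            stim, params, rng, phase=row.phase, timeout_ms=trial_timeout
        )
        tcol, trow = stim.target.cell if stim.target.cell is not None else (None, None)
        records.append(
            TrialRecord(
                participant=participant, trial=int(row.trial), phase=row.phase,
                block=int(row.block), condition=row.condition,
                configuration=row.configuration, target_present=bool(row.target_present),
                target_half=row.target_half, target_col=tcol, target_row=trow,
                response=response, correct=correct, rt_ms=rt, stim_seed=stim_seed,
                fixations=fixations,
            )
        )
    return records


def sample_population(
    n: int,
    spec: PopulationSpec | None = None,
    seed: int = 0,
) -> list[ObserverParams]:
    """Draw a cohort of i.i.d. observers from the population distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = PopulationSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        if spec.w_het_fixed is not None:
            w = spec.w_het_fixed
        else:
            a, b = spec.w_het_beta
            w = float(rng.beta(a, b))
        cohort.append(replace(spec.template, w_het=w, seed=int(rng.integers(0, 2**31 - 1))))
    return cohort


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to one row per fixation (fix_index is 1-based)."""
    rows = []
    for r in records:
        base = dict(
            participant=r.participant, trial=r.trial, phase=r.phase, block=r.block,
            condition=r.condition, configuration=r.configuration,
            target_present=r.target_present, target_half=r.target_half,
            target_col=r.target_col, target_row=r.target_row, response=r.response,
            correct=r.correct, rt_ms=r.rt_ms, stim_seed=r.stim_seed,
        )
        for i, (x, y, dur) in enumerate(r.fixations, start=1):
            rows.append(dict(base, fix_index=i, x_px=x, y_px=y, dur_ms=dur))
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame["correct"] = frame["correct"].astype("boolean")
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`records_to_frame` (order-preserving)."""
    records = []
    for (participant, trial), sub in frame.groupby(["participant", "trial"], sort=False):
        sub = sub.sort_values("fix_index")
        first = sub.iloc[0]
        correct = first["correct"]
        tcol, trow = first["target_col"], first["target_row"]
        records.append(
            TrialRecord(
                participant=str(participant), trial=int(trial), phase=str(first["phase"]),
                block=int(first["block"]), condition=str(first["condition"]),
                configuration=str(first["configuration"]),
                target_present=bool(first["target_present"]),
                target_half=str(first["target_half"]),
                target_col=None if pd.isna(tcol) else int(tcol),
                target_row=None if pd.isna(trow) else int(trow),
                response=str(first["response"]),
                correct=None if pd.isna(correct) else bool(correct),
                rt_ms=float(first["rt_ms"]), stim_seed=int(first["stim_seed"]),
                fixations=[
                    (float(x), float(y), float(d))
                    for x, y, d in zip(sub["x_px"], sub["y_px"], sub["dur_ms"])
                ],
            )
        )
    return records


def write_fixation_report(records: list[TrialRecord], path: str | Path) -> None:
    """Write the flat fixation report (tab-delimited; header always present)."""
    frame = records_to_frame(records)
    frame.to_csv(Path(path), sep="\t", index=False)
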