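"""Preprocessing, fixation classification, exclusions and the efficiency score.

Every fixation gets exactly one label: ``heterogeneous``, ``homogeneous``,
``unclassified`` (within the central strip of a split-half display) or
``out_of_bounds`` (outside the array extent; excluded from all counts).

The search-strategy statistic ("efficiency") pools classified fixations
2-6 over correct target-absent trials and reports the fraction that landed
on heterogeneous regions: n_het / (n_het + n_homo), with 1 = optimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .observers import REPORT_COLUMNS, TrialRecord, frame_to_records, stimulus_for_trial
from .stimgen import EXP1_GRID, EXP2_GRID, GridSpec, StimulusArray

__all__ = [
    "LABEL_HET",
    "LABEL_HOMO",
    "LABEL_UNCLASSIFIED",
    "LABEL_OOB",
    "DEFAULT_STRIP_PX",
    "DEFAULT_THRESHOLD",
    "grid_for",
    "read_fixation_frame",
    "read_fixation_report",
    "mark_out_of_bounds",
    "classify_split_half",
    "classify_jumbled",
    "classify_frame",
    "filter_strategy_fixations",
    "efficiency_score",
    "trial_table",
    "accuracy_rt_tables",
    "participant_accuracy",
    "apply_exclusions",
    "accuracy_by_target_difficulty",
    "summarize_participants",
]

LABEL_HET = "heterogeneous"
LABEL_HOMO = "homogeneous"
LABEL_UNCLASSIFIED = "unclassified"
LABEL_OOB = "out_of_bounds"

#: Total width of the unclassified strip straddling the split midline.
DEFAULT_STRIP_PX = 30.0
#: Cell-difficulty cut between homogeneous and heterogeneous regions.
DEFAULT_THRESHOLD = 0.5

_NUMERIC_REQUIRED = ["trial", "block", "rt_ms", "stim_seed", "fix_index", "x_px", "y_px", "dur_ms"]
_NUMERIC_OPTIONAL = ["target_col", "target_row"]
_BOOL_TRUE = {"true", "1"}
_BOOL_FALSE = {"false", "0"}


def grid_for(experiment: str) -> GridSpec:
    if experiment == "exp1":
        return EXP1_GRID
    if experiment == "exp2":
        return EXP2_GRID
    raise ValueError(f"unknown experiment {experiment!r}")


def _parse_bool(series: pd.Series, column: str, allow_missing: bool) -> pd.Series:
    lowered = series.str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[lowered.isin(_BOOL_TRUE)] = True
    out[lowered.isin(_BOOL_FALSE)] = False
    bad = out.isna() & (lowered != "") if allow_missing else out.isna()
    if bad.any():
        rows = [int(i) + 2 for i in series.index[bad][:5]]  # +2: header + 1-based
        raise ValueError(f"invalid boolean value in column {column!r} at file row(s) {rows}")
    return out


def read_fixation_frame(path: str | Path) -> pd.DataFrame:
    """Read and validate a fixation report.

    Raises ``ValueError`` naming any missing column, and row-numbered errors
    for malformed (non-numeric / non-boolean) values.
    """
    raw = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"fixation report is missing column(s): {', '.join(missing)}")
    out = pd.DataFrame(index=raw.index)
    for col in ("participant", "phase", "condition", "configuration", "target_half", "response"):
        out[col] = raw[col]
    for col in _NUMERIC_REQUIRED + _NUMERIC_OPTIONAL:
        values = raw[col].str.strip()
        empty = values == ""
        try:
            # numpy's parser is correctly rounded (lossless float round-trip)
            arr = np.where(empty, "nan", values).astype(float)
            converted = pd.Series(arr, index=raw.index)
            bad = pd.Series(False, index=raw.index)
        except ValueError:
            converted = pd.to_numeric(values.replace("", np.nan), errors="coerce")
            bad = converted.isna() & ~empty
        if col in _NUMERIC_REQUIRED:
            bad = bad | empty
        if bad.any():
            rows = [int(i) + 2 for i in raw.index[bad][:5]]
            raise ValueError(f"non-numeric value in column {col!r} at file row(s) {rows}")
        out[col] = converted
    out["target_present"] = _parse_bool(raw["target_present"], "target_present", False)
    out["correct"] = _parse_bool(raw["correct"], "correct", True)
    for col in ("trial", "block", "stim_seed", "fix_index"):
        out[col] = out[col].astype(int)
    out["target_present"] = out["target_present"].astype(bool)
    return out[REPORT_COLUMNS]


def read_fixation_report(path: str | Path) -> list[TrialRecord]:
    """Read a fixation report back into trial records (writer round-trip)."""
    return frame_to_records(read_fixation_frame(path))


def mark_out_of_bounds(x: float, y: float, grid: GridSpec) -> bool:
    """True when the fixation falls outside [origin, origin + extent)."""
    return not grid.contains(x, y)


def classify_split_half(
    x: float,
    y: float,
    configuration: str,
    grid: GridSpec,
    strip_px: float = DEFAULT_STRIP_PX,
) -> str:
    """Label a fixation on a split-half display by side of the midline.

    Fixations within the central strip (total width ``strip_px``, half-open
    interval [midline - strip/2, midline + strip/2)) are left unclassified.
    The strip runs along the split boundary: horizontal for up/down splits,
    vertical for left/right splits.
    """
    cx, cy = grid.centre_px
    if configuration in ("hard_up", "hard_down"):
        d = y - cy
        het_on_negative_side = configuration == "hard_up"
    elif configuration in ("hard_left", "hard_right"):
        d = x - cx
        het_on_negative_side = configuration == "hard_left"
    else:
        raise ValueError(f"unknown split-half configuration {configuration!r}")
    if -strip_px / 2 <= d < strip_px / 2:
        return LABEL_UNCLASSIFIED
    return LABEL_HET if (d < 0) == het_on_negative_side else LABEL_HOMO


def classify_jumbled(
    x: float,
    y: float,
    stim: StimulusArray,
    threshold: float = DEFAULT_THRESHOLD,
) -> str:
    """Label a fixation by the difficulty of the fixated cell.

    Heterogeneous iff difficulty strictly exceeds the threshold (ties go to
    homogeneous).  Out-of-bounds fixations must be filtered beforehand.
    """
    cell = stim.grid.cell_at(x, y)
    if cell is None:
        raise ValueError("fixation is outside the array; filter out_of_bounds first")
    col, row = cell
    return LABEL_HET if stim.cell_difficulty[row, col] > threshold else LABEL_HOMO


def classify_frame(
    frame: pd.DataFrame,
    experiment: str,
    strip_px: float = DEFAULT_STRIP_PX,
    threshold: float = DEFAULT_THRESHOLD,
    stim_cache: dict[int, StimulusArray] | None = None,
) -> pd.DataFrame:
    """Vectorised classification of a whole fixation report.

    Returns a copy of the frame with a ``label`` column.  Jumbled-condition
    stimuli are rebuilt deterministically from ``stim_seed`` unless supplied
    via ``stim_cache``.
    """
    grid = grid_for(experiment)
    out = frame.copy()
    x = out["x_px"].to_numpy(dtype=float)
    y = out["y_px"].to_numpy(dtype=float)
    labels = np.full(len(out), LABEL_UNCLASSIFIED, dtype=object)

    ox, oy = grid.origin_px
    w, h = grid.extent_px
    inb = (x >= ox) & (x < ox + w) & (y >= oy) & (y < oy + h)
    labels[~inb] = LABEL_OOB

    cond = out["condition"].to_numpy()
    cx, cy = grid.centre_px

    split = inb & (cond == "split_half")
    if split.any():
        for config in pd.unique(out.loc[split, "configuration"]):
            sel = split & (out["configuration"].to_numpy() == config)
            if config in ("hard_up", "hard_down"):
                d = y[sel] - cy
                het_neg = config == "hard_up"
            elif config in ("hard_left", "hard_right"):
                d = x[sel] - cx
                het_neg = config == "hard_left"
            else:
                raise ValueError(f"unknown split-half configuration {config!r}")
            lab = np.where((d < 0) == het_neg, LABEL_HET, LABEL_HOMO)
            lab[(d >= -strip_px / 2) & (d < strip_px / 2)] = LABEL_UNCLASSIFIED
            labels[sel] = lab

    labels[inb & (cond == "easy")] = LABEL_HOMO
    labels[inb & (cond == "hard")] = LABEL_HET

    jumbled = inb & (cond == "jumbled")
    if jumbled.any():
        cache = {} if stim_cache is None else stim_cache
        idx = np.nonzero(jumbled)[0]
        for seed_val in pd.unique(out.iloc[idx]["stim_seed"]):
            sel = idx[out.iloc[idx]["stim_seed"].to_numpy() == seed_val]
            stim = cache.get(int(seed_val))
            if stim is None:
                first = out.iloc[sel[0]]
                stim = stimulus_for_trial(
                    experiment, "jumbled", str(first["configuration"]),
                    bool(first["target_present"]), str(first["target_half"]),
                    int(seed_val),
                )
                cache[int(seed_val)] = stim
            col = ((x[sel] - ox) // grid.cell_px).astype(int)
            row = ((y[sel] - oy) // grid.cell_px).astype(int)
            diff = stim.cell_difficulty[row, col]
            labels[sel] = np.where(diff > threshold, LABEL_HET, LABEL_HOMO)

    out["label"] = labels
    return out


def filter_strategy_fixations(
    classified: pd.DataFrame,
    fix_range: tuple[int, int] = (2, 6),
) -> pd.DataFrame:
    """Classified fixations entering the strategy score.

    Keeps search-phase, correct, target-absent trials; fixation indices in
    ``fix_range`` (inclusive); heterogeneous/homogeneous labels only.
    """
    lo, hi = fix_range
    correct = classified["correct"].fillna(False).astype(bool)
    keep = (
        (classified["phase"] == "search")
        & ~classified["target_present"].astype(bool)
        & correct
        & classified["fix_index"].between(lo, hi)
        & classified["label"].isin([LABEL_HET, LABEL_HOMO])
    )
    return classified.loc[keep]


def efficiency_score(
    classified: pd.DataFrame,
    fix_range: tuple[int, int] = (2, 6),
    by: tuple[str, ...] = ("participant",),
) -> pd.DataFrame:
    """Pooled-count efficiency per group: n_het / (n_het + n_homo).

    Groups with an empty denominator are flagged ``undefined`` with NaN
    efficiency (never reported as 0).  Every group present in the
    search-phase input appears in the output.
    """
    pooled = filter_strategy_fixations(classified, fix_range)
    het = (pooled["label"] == LABEL_HET).groupby([pooled[c] for c in by]).sum()
    tot = pooled.groupby(list(by)).size()
    base = classified.loc[classified["phase"] == "search", list(by)].drop_duplicates()
    out = base.set_index(list(by)).sort_index()
    out["n_het"] = het.reindex(out.index).fillna(0).astype(int)
    out["n_homo"] = (tot.reindex(out.index).fillna(0) - out["n_het"]).astype(int)
    denom = out["n_het"] + out["n_homo"]
    out["efficiency"] = np.where(denom > 0, out["n_het"] / denom.replace(0, np.nan), np.nan)
    out["undefined"] = denom == 0
    return out.reset_index()


def trial_table(frame: pd.DataFrame) -> pd.DataFrame:
    """One row per (participant, trial) with trial-level fields."""
    cols = [
        "participant", "trial", "phase", "block", "condition", "configuration",
        "target_present", "target_half", "target_col", "target_row",
        "response", "correct", "rt_ms", "stim_seed",
    ]
    return frame[cols].drop_duplicates(subset=["participant", "trial"]).reset_index(drop=True)


def accuracy_rt_tables(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy and median RT by condition and target presence.

    Accuracy is the fraction of correct responses over all search trials in
    the cell; median RT is taken over correct trials only.
    """
    trials = trial_table(frame)
    trials = trials[trials["phase"] == "search"].copy()
    trials["correct"] = trials["correct"].fillna(False).astype(bool)
    keys = ["participant", "condition", "target_present"]
    acc = trials.groupby(keys, as_index=False).agg(
        n_trials=("correct", "size"), accuracy=("correct", "mean")
    )
    rt = (
        trials[trials["correct"]]
        .groupby(keys, as_index=False)
        .agg(median_rt_ms=("rt_ms", "median"))
    )
    return acc.merge(rt, on=keys, how="left")


def participant_accuracy(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-participant target-absent and hard-target-present accuracy."""
    trials = trial_table(frame)
    trials = trials[trials["phase"] == "search"].copy()
    trials["correct"] = trials["correct"].fillna(False).astype(bool)
    ta = (
        trials[~trials["target_present"]]
        .groupby("participant")["correct"].mean()
        .rename("ta_accuracy")
    )
    hard = trials["target_present"] & (
        (trials["condition"] == "hard") | (trials["target_half"] == "hard")
    )
    hard_acc = (
        trials[hard].groupby("participant")["correct"].mean().rename("hard_tp_accuracy")
    )
    participants = trials["participant"].drop_duplicates().sort_values()
    out = pd.DataFrame({"participant": participants.to_numpy()})
    out = out.merge(ta, on="participant", how="left")
    out = out.merge(hard_acc, on="participant", how="left")
    return out


def apply_exclusions(
    accuracy: pd.DataFrame,
    experiment: str,
    ta_threshold: float = 0.75,
    hard_threshold: float = 0.25,
) -> pd.DataFrame:
    """Flag participants failing the pre-specified accuracy criteria.

    Both experiments exclude target-absent accuracy strictly below
    ``ta_threshold``; exp2 additionally excludes hard-target-present
    accuracy strictly below ``hard_threshold``.  Flagged participants are
    retained in the table (``excluded`` + ``exclusion_reason`` columns).
    """
    out = accuracy.copy()
    reasons = []
    for row in out.itertuples(index=False):
        why = []
        if pd.notna(row.ta_accuracy) and row.ta_accuracy < ta_threshold:
            why.append(f"ta_accuracy<{ta_threshold}")
        if (
            experiment == "exp2"
            and pd.notna(row.hard_tp_accuracy)
            and row.hard_tp_accuracy < hard_threshold
        ):
            why.append(f"hard_tp_accuracy<{hard_threshold}")
        reasons.append(";".join(why))
    out["excluded"] = [bool(r) for r in reasons]
    out["exclusion_reason"] = reasons
    return out


def accuracy_by_target_difficulty(
    frame: pd.DataFrame,
    experiment: str,
    bin_width: float = 0.1,
    stim_cache: dict[int, StimulusArray] | None = None,
) -> pd.DataFrame:
    """Jumbled target-present accuracy binned by target-cell difficulty."""
    trials = trial_table(frame)
    trials = trials[
        (trials["phase"] == "search")
        & (trials["condition"] == "jumbled")
        & trials["target_present"]
    ].copy()
    if trials.empty:
        return pd.DataFrame(columns=["difficulty_bin", "n_trials", "accuracy"])
    cache = {} if stim_cache is None else stim_cache
    difficulties = []
    for row in trials.itertuples(index=False):
        stim = cache.get(int(row.stim_seed))
        if stim is None:
            stim = stimulus_for_trial(
                experiment, "jumbled", row.configuration, True, row.target_half,
                int(row.stim_seed),
            )
            cache[int(row.stim_seed)] = stim
        col, rw = stim.target.cell
        difficulties.append(float(stim.cell_difficulty[rw, col]))
    trials["target_difficulty"] = difficulties
    n_bins = int(round(1.0 / bin_width))
    trials["difficulty_bin"] = np.clip(
        (trials["target_difficulty"] // bin_width).astype(int), 0, n_bins - 1
    ) * bin_width
    trials["correct"] = trials["correct"].fillna(False).astype(bool)
    return trials.groupby("difficulty_bin", as_index=False).agg(
        n_trials=("correct", "size"), accuracy=("correct", "mean")
    )


def summarize_participants(
    classified: pd.DataFrame,
    experiment: str,
    fix_range: tuple[int, int] = (2, 6),
) -> pd.DataFrame:
    """Per-participant strategy summary: efficiency, accuracy, exclusions."""
    eff = efficiency_score(classified, fix_range)
    acc = participant_accuracy(classified)
    flagged = apply_exclusions(acc, experiment)
    return eff.merge(flagged, on="participant", how="outer")
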