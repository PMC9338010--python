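"""Group-level summaries and the parameter-recovery harness.

Provides per-fixation-index strategy curves, interval estimates for the
probability of fixating heterogeneous regions by task and spatial
configuration, correlation reports for log2 median reaction times, and an
end-to-end recovery experiment that checks the whole
generate -> simulate -> classify -> score chain against the generating
observer parameters.

The interval backend is a participant-level (cluster) bootstrap: cell
estimates are means of per-participant proportions, with intervals of the
form mean +/- t_{k-1} * sd(bootstrap means).  This dependency-light backend
stands in for a hierarchical logistic model; its contract is the
calibration property (~95% nominal coverage of the generating probability).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import observers as obs
from . import pipeline as pipe

__all__ = [
    "HierarchicalResult",
    "CorrelationReport",
    "RecoveryReport",
    "strategy_by_index",
    "hierarchical_proportion",
    "fisher_ci",
    "rt_correlations",
    "recovery_experiment",
    "coverage_simulation",
]


@dataclass(frozen=True)
class HierarchicalResult:
    """Interval estimates per factor cell and for pairwise cell differences."""

    cells: pd.DataFrame
    differences: pd.DataFrame


@dataclass(frozen=True)
class CorrelationReport:
    """Condition-pair correlations of log2 median RTs plus strategy correlation."""

    ta_matrix: pd.DataFrame
    tp_matrix: pd.DataFrame
    strategy_r: float | None
    strategy_ci: tuple[float, float] | None
    n_participants: int


@dataclass(frozen=True)
class RecoveryReport:
    condition: str
    table: pd.DataFrame  # per-w_het recovery summary
    max_abs_bias: float
    rmse: float


def strategy_by_index(
    classified: pd.DataFrame,
    fix_range: tuple[int, int] = (2, 6),
    by: tuple[str, ...] = ("participant", "configuration"),
) -> pd.DataFrame:
    """Proportion of heterogeneous fixations at each fixation index.

    Uses the same trial filter as the efficiency score, but keeps per-index
    denominators: a trial whose index-i fixation is unclassified drops out
    of index i only.
    """
    pooled = pipe.filter_strategy_fixations(classified, fix_range)
    keys = [*by, "fix_index"]
    grouped = pooled.assign(het=pooled["label"] == pipe.LABEL_HET).groupby(
        keys, as_index=False
    )
    return grouped.agg(n=("het", "size"), prop_het=("het", "mean"))


def _interval(ps: np.ndarray, rng: np.random.Generator, n_boot: int, level: float,
              ns: np.ndarray | None = None, clip: tuple[float, float] | None = (0.0, 1.0)):
    """Cluster-bootstrap interval for the mean of per-participant values."""
    k = ps.size
    est = float(ps.mean())
    if k == 1:
        # single-participant limit: Wald interval on the pooled proportion
        n = float(ns[0]) if ns is not None else 1.0
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(max(est * (1 - est), 0.0) / n)
        lo, hi = est - half, est + half
    else:
        idx = rng.integers(0, k, size=(n_boot, k))
        means = ps[idx].mean(axis=1)
        sd = float(means.std(ddof=1))
        tcrit = stats.t.ppf(0.5 + level / 2, df=k - 1)
        lo, hi = est - tcrit * sd, est + tcrit * sd
    if clip is not None:
        lo, hi = max(lo, clip[0]), min(hi, clip[1])
    return est, lo, hi


def hierarchical_proportion(
    classified: pd.DataFrame,
    factors: tuple[str, ...] = ("phase", "configuration"),
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> HierarchicalResult:
    """Interval estimates of P(fixation heterogeneous) per factor cell.

    Per-participant proportions of heterogeneous labels are computed within
    each factor cell; cell estimates are their means with cluster-bootstrap
    intervals, and pairwise cell differences use participant-paired
    differences.  Degenerate cells (a single label across the board) yield
    boundary intervals with a warning.
    """
    lab = classified[classified["label"].isin([pipe.LABEL_HET, pipe.LABEL_HOMO])]
    if lab.empty:
        raise ValueError("no classified heterogeneous/homogeneous fixations")
    het = lab["label"] == pipe.LABEL_HET
    counts = (
        lab.assign(het=het)
        .groupby(["participant", *factors])
        .agg(n_het=("het", "sum"), n=("het", "size"))
        .reset_index()
    )
    counts["p"] = counts["n_het"] / counts["n"]
    rng = np.random.default_rng(seed)

    cell_rows = []
    props: dict[tuple, pd.Series] = {}
    for key, sub in counts.groupby(list(factors), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ps = sub.set_index("participant")["p"]
        props[key] = ps
        est, lo, hi = _interval(
            ps.to_numpy(), rng, n_boot, level, ns=sub["n"].to_numpy()
        )
        if est in (0.0, 1.0):
            warnings.warn(
                f"degenerate cell {key}: all fixations share one label; "
                "interval pinned to the boundary",
                stacklevel=2,
            )
        cell_rows.append(dict(zip(factors, key), estimate=est, lower=lo, upper=hi,
                              n_participants=len(ps)))
    cells = pd.DataFrame(cell_rows)

    diff_rows = []
    for key_a, key_b in itertools.combinations(sorted(props), 2):
        pa, pb = props[key_a], props[key_b]
        common = pa.index.intersection(pb.index)
        if len(common) < 2:
            continue
        diffs = (pa.loc[common] - pb.loc[common]).to_numpy()
        est, lo, hi = _interval(diffs, rng, n_boot, level, clip=(-1.0, 1.0))
        diff_rows.append(
            dict(
                cell_a="/".join(map(str, key_a)), cell_b="/".join(map(str, key_b)),
                estimate=est, lower=lo, upper=hi, n_participants=len(common),
            )
        )
    differences = pd.DataFrame(
        diff_rows,
        columns=["cell_a", "cell_b", "estimate", "lower", "upper", "n_participants"],
    )
    return HierarchicalResult(cells=cells, differences=differences)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))


def rt_correlations(
    rt_table: pd.DataFrame,
    efficiency_table: pd.DataFrame | None = None,
    conditions: tuple[str, ...] = ("easy", "hard", "split_half", "jumbled"),
    level: float = 0.95,
) -> CorrelationReport:
    """Pearson correlations of log2 median RT across conditions.

    ``rt_table`` must have columns participant, condition, target_present,
    median_rt_ms (the :func:`visearch.pipeline.accuracy_rt_tables` layout);
    matrices are computed separately for target-absent and target-present
    trials.  If ``efficiency_table`` (participant, condition, efficiency) is
    given, the split-half vs jumbled strategy correlation is reported with a
    Fisher-z interval.
    """
    matrices = {}
    n_used = 0
    for present in (False, True):
        sub = rt_table[rt_table["target_present"] == present]
        wide = sub.pivot_table(
            index="participant", columns="condition", values="median_rt_ms"
        ).reindex(columns=list(conditions))
        wide = wide.dropna()
        if len(wide) < 3:
            raise ValueError("rt_correlations requires at least 3 complete participants")
        n_used = max(n_used, len(wide))
        matrices[present] = np.log2(wide).corr(method="pearson")

    strategy_r = strategy_ci = None
    if efficiency_table is not None:
        wide = efficiency_table.pivot_table(
            index="participant", columns="condition", values="efficiency"
        )
        if {"split_half", "jumbled"}.issubset(wide.columns):
            pair = wide[["split_half", "jumbled"]].dropna()
            if len(pair) >= 4:
                strategy_r = float(
                    stats.pearsonr(pair["split_half"], pair["jumbled"]).statistic
                )
                strategy_ci = fisher_ci(strategy_r, len(pair), level)
    return CorrelationReport(
        ta_matrix=matrices[False], tp_matrix=matrices[True],
        strategy_r=strategy_r, strategy_ci=strategy_ci, n_participants=n_used,
    )


def _ta_trial_records(
    participant: str,
    stimuli: list,
    params: obs.ObserverParams,
    rng: np.random.Generator,
    n_trials: int,
) -> list[obs.TrialRecord]:
    records = []
    for t in range(n_trials):
        stim = stimuli[int(rng.integers(len(stimuli)))]
        response, correct, rt, fixations = obs.simulate_trial(stim, params, rng)
        records.append(
            obs.TrialRecord(
                participant=participant, trial=t, phase="search", block=1,
                condition=stim.condition, configuration=stim.configuration,
                target_present=False, target_half="absent",
                target_col=None, target_row=None, response=response,
                correct=correct, rt_ms=rt, stim_seed=stim.seed, fixations=fixations,
            )
        )
    return records


def recovery_experiment(
    condition: str = "split_half",
    w_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_observers: int = 20,
    n_trials: int = 80,
    seed: int = 0,
    n_stimuli: int = 40,
    template: obs.ObserverParams | None = None,
) -> RecoveryReport:
    """End-to-end recovery of ``w_het`` from target-absent sessions.

    For each value on ``w_grid`` a cohort of identical observers is
    simulated on target-absent trials (split-half stimuli use the exp1
    up/down geometry, jumbled the exp2 grid); the fixation report is run
    through the classification pipeline and the mean recovered efficiency
    is compared with the generating ``w_het``.  A shared stimulus pool is
    reused across observers to keep the run inside a desk-scale budget;
    everything derives from ``seed``.
    """
    if condition not in ("split_half", "jumbled"):
        raise ValueError("recovery supports split_half or jumbled conditions")
    experiment = "exp1" if condition == "split_half" else "exp2"
    if template is None:
        template = obs.ObserverParams()
    rng = np.random.default_rng(seed)

    if condition == "split_half":
        stimuli = [
            obs.stimulus_for_trial(
                "exp1", "split_half", config, False, "absent",
                int(rng.integers(0, 2**31 - 1)),
            )
            for config in ("hard_up", "hard_down")
        ]
    else:
        stimuli = [
            obs.stimulus_for_trial(
                "exp2", "jumbled", "none", False, "absent",
                int(rng.integers(0, 2**31 - 1)),
            )
            for _ in range(n_stimuli)
        ]
    cache = {s.seed: s for s in stimuli}

    records = []
    truth = {}
    for w in w_grid:
        params = replace(template, w_het=float(w))
        for i in range(n_observers):
            pid = f"w{w:.2f}_p{i:02d}"
            truth[pid] = float(w)
            records.extend(_ta_trial_records(pid, stimuli, params, rng, n_trials))

    frame = obs.records_to_frame(records)
    classified = pipe.classify_frame(frame, experiment, stim_cache=cache)
    eff = pipe.efficiency_score(classified)
    eff["w_true"] = eff["participant"].map(truth)

    per_w = eff.groupby("w_true", as_index=False).agg(
        recovered=("efficiency", "mean"),
        sd=("efficiency", "std"),
        n_observers=("efficiency", "size"),
    )
    per_w["bias"] = per_w["recovered"] - per_w["w_true"]
    rmse = float(np.sqrt(np.mean((eff["efficiency"] - eff["w_true"]) ** 2)))
    return RecoveryReport(
        condition=condition,
        table=per_w,
        max_abs_bias=float(per_w["bias"].abs().max()),
        rmse=rmse,
    )


def coverage_simulation(
    true_p: float = 0.5,
    n_participants: int = 13,
    n_fixations: int = 80,
    n_replicates: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Interval-calibration check for :func:`hierarchical_proportion`.

    Each replicate draws per-participant binomial fixation labels at the
    true probability, builds a single-cell classified frame, fits the
    interval and records whether it covers ``true_p``.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    widths = []
    for rep in range(n_replicates):
        n_het = rng.binomial(n_fixations, true_p, size=n_participants)
        rows = []
        for i, k in enumerate(n_het):
            labels = [pipe.LABEL_HET] * int(k) + [pipe.LABEL_HOMO] * (n_fixations - int(k))
            rows.extend(
                dict(participant=f"p{i:02d}", phase="search", configuration="hard_up",
                     label=lab)
                for lab in labels
            )
        frame = pd.DataFrame(rows)
        result = hierarchical_proportion(
            frame, factors=("configuration",), n_boot=n_boot,
            seed=int(rng.integers(0, 2**31 - 1)), level=level,
        )
        row = result.cells.iloc[0]
        if row["lower"] <= true_p <= row["upper"]:
            covered += 1
        widths.append(row["upper"] - row["lower"])
    return {
        "coverage": covered / n_replicates,
        "mean_width": float(np.mean(widths)),
        "n_replicates": n_replicates,
    }
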