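"""Algorithm-selection metrics and portfolio diagnostics.

Core quantities: the single best solver (SBS, best mean-performance column),
the virtual best solver (VBS, per-instance oracle), VBS@K order statistics,
Selected@K frequency ranks, and the fraction of the VBS-SBS gap a selector
closes, ``100 * (AS - SBS) / (VBS - SBS)``.

Diagnostics: rank stability between two protocols (Spearman rho and
tie-corrected Kendall tau_b over mean-score solver rankings, plus top-k
Jaccard overlaps), oracle-winner entropy, margin-based reliability in
equal-mass bins, and selection-frequency distributions.

The rank correlations are implemented here tie-aware from first principles
(small m makes the O(m^2) pair enumeration trivial); tests cross-check them
against scipy.stats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import PerformanceTable
from .selector import PredictionVector

__all__ = [
    "EvalReport",
    "StabilityReport",
    "sbs",
    "vbs_curve",
    "vbs_at_k",
    "selected_at_k",
    "gap_closed",
    "improvement",
    "rank_stability",
    "vbs_entropy",
    "margin_reliability",
    "selection_distribution",
    "evaluate",
]


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def sbs(table: PerformanceTable, metric: str = "relaxed") -> int:
    """Index of the single best solver: argmax column mean, earliest on ties."""
    if table.n < 1:
        raise ValueError("empty performance table")
    means = table.metric_matrix(metric).mean(axis=0)
    return int(np.argmax(means))


def vbs_curve(table: PerformanceTable, metric: str = "relaxed"):
    """Per-instance oracle performance (row maxima) and its mean."""
    if table.n < 1:
        raise ValueError("empty performance table")
    per_instance = table.metric_matrix(metric).max(axis=1)
    return per_instance, float(per_instance.mean())


def vbs_at_k(table: PerformanceTable, k: int, metric: str = "relaxed"):
    """Per-instance k-th best solver performance (k=1 is the oracle)."""
    if not 1 <= k <= table.m:
        raise ValueError(f"k must be in [1, {table.m}], got {k}")
    mat = np.sort(table.metric_matrix(metric), axis=1)[:, ::-1]
    per_instance = mat[:, k - 1]
    return per_instance, float(per_instance.mean())


def selected_at_k(selections, k: int):
    """k-th most frequently selected solver and its count (ties -> earliest index)."""
    sel = np.asarray(selections, dtype=int)
    idx, counts = np.unique(sel, return_counts=True)
    if not 1 <= k <= len(idx):
        raise ValueError(f"k={k} exceeds the {len(idx)} distinct selected solvers")
    # sort by count descending, then solver index ascending
    order = np.lexsort((idx, -counts))
    winner = idx[order[k - 1]]
    return int(winner), int(counts[order[k - 1]])


def gap_closed(as_perf: float, sbs_perf: float, vbs_perf: float) -> float:
    """Percent of the VBS-SBS gap closed; NaN (with warning) when VBS == SBS.

    Negative values mean the selector widened the gap below the SBS baseline.
    """
    if vbs_perf < sbs_perf:
        raise ValueError("VBS performance below SBS violates the oracle bound")
    if vbs_perf == sbs_perf:
        warnings.warn("degenerate benchmark: VBS == SBS, gap closure undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * (as_perf - sbs_perf) / (vbs_perf - sbs_perf)


def improvement(as_perf: float, sbs_perf: float) -> float:
    """Absolute improvement over SBS in percentage points."""
    return as_perf - sbs_perf


# ---------------------------------------------------------------------------
# rank stability
# ---------------------------------------------------------------------------

def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average rank for ties), 1-based."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of midranks."""
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return float("nan")
    return float(rx @ ry) / denom


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall tau_b by O(m^2) pair enumeration."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx == dy:
                concordant += 1
            else:
                discordant += 1
    denom = math.sqrt((concordant + discordant + ties_x)
                      * (concordant + discordant + ties_y))
    if denom == 0.0:
        return float("nan")
    return (concordant - discordant) / denom


def _top_k_set(means: np.ndarray, k: int) -> set:
    """Top-k solver set by descending mean, ties broken by solver index."""
    order = np.lexsort((np.arange(len(means)), -means))
    return set(int(i) for i in order[:k])


@dataclass
class StabilityReport:
    spearman_rho: float
    kendall_tau_b: float
    jk_curve: np.ndarray            # jk_curve[k-1] = top-k Jaccard, k = 1..m

    @property
    def j1(self) -> float:
        return float(self.jk_curve[0])

    @property
    def jbar(self) -> float:
        return float(self.jk_curve.mean())


def rank_stability(table_p: PerformanceTable, table_q: PerformanceTable,
                   metric: str = "mean_score") -> StabilityReport:
    """Solver-ranking agreement between two protocols sharing one portfolio.

    Rankings are induced by per-solver column means of the composite score
    (``metric='mean_score'``; success-indicator variants available).  J_k is
    the Jaccard overlap of the two top-k solver sets for k = 1..m.
    """
    if table_p.portfolio.solver_ids != table_q.portfolio.solver_ids:
        raise ValueError("rank_stability requires identical portfolios (same solver order)")
    mp = table_p.metric_matrix(metric).mean(axis=0)
    mq = table_q.metric_matrix(metric).mean(axis=0)
    m = len(mp)
    jk = np.empty(m)
    for k in range(1, m + 1):
        sp, sq = _top_k_set(mp, k), _top_k_set(mq, k)
        jk[k - 1] = len(sp & sq) / len(sp | sq)
    return StabilityReport(
        spearman_rho=_spearman(mp, mq),
        kendall_tau_b=_kendall_tau_b(mp, mq),
        jk_curve=jk,
    )


# ---------------------------------------------------------------------------
# oracle-winner dispersion
# ---------------------------------------------------------------------------

def vbs_entropy(table: PerformanceTable, metric: str = "mean_score") -> float:
    """Shannon entropy (bits) of the oracle-winner distribution.

    Rows whose maximum is attained by several solvers split their unit mass
    fractionally among the tied winners.  0 bits means one solver dominates
    every instance; log2(m) is the uniform-winner ceiling.
    """
    if table.n < 1:
        raise ValueError("empty performance table")
    mat = table.metric_matrix(metric)
    row_max = mat.max(axis=1, keepdims=True)
    winners = mat == row_max
    mass = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0)
    p = mass / mass.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------------
# selector diagnostics
# ---------------------------------------------------------------------------

def _oracle_agreement(selected: int, row: np.ndarray) -> bool:
    """Selected solver attains the row maximum (any tied maximum counts)."""
    return row[selected] == row.max()


def margin_reliability(predictions: list[PredictionVector], table: PerformanceTable,
                       n_bins: int = 12) -> list[dict]:
    """Reliability statistics over equal-mass bins of the prediction margin.

    Predictions are sorted by margin (ascending); remainder instances go to
    the lowest-margin bins.  Per bin: oracle agreement rate
    P(selected = VBS winner), and advantage rates P(s_sel > s_SBS) /
    P(s_sel >= s_SBS) against the composite-score SBS column.
    """
    n = table.n
    if len(predictions) != n:
        raise ValueError("predictions must align with table rows")
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} instances, got {n}")
    margins = np.array([p.margin for p in predictions])
    selected = np.array([p.selected for p in predictions])
    order = np.argsort(margins, kind="stable")
    base = n // n_bins
    rem = n % n_bins
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    sbs_idx = sbs(table, "mean_score")
    scores = table.scores
    report = []
    start = 0
    for b, size in enumerate(sizes):
        idx = order[start:start + size]
        start += size
        sel = selected[idx]
        rows = scores[idx]
        s_sel = rows[np.arange(size), sel]
        s_sbs = rows[:, sbs_idx]
        agree = [_oracle_agreement(s, r) for s, r in zip(sel, rows)]
        report.append({
            "bin": b,
            "n": int(size),
            "margin_lo": float(margins[idx].min()),
            "margin_hi": float(margins[idx].max()),
            "p_oracle_agree": float(np.mean(agree)),
            "p_beats_sbs": float(np.mean(s_sel > s_sbs)),
            "p_matches_sbs": float(np.mean(s_sel >= s_sbs)),
        })
    return report


def selection_distribution(predictions: list[PredictionVector], table: PerformanceTable,
                           top: int = 3) -> dict:
    """Selector vs oracle selection frequencies and realised success rates.

    Reports, for the ``top`` most frequently selected solvers: the selector's
    selection frequency, the oracle-winner frequency (fractional tie split)
    for the same solvers, the solver's realised relaxed success rate, plus
    the per-instance top-1 oracle-agreement flags and overall frequencies.
    """
    n = table.n
    if len(predictions) != n:
        raise ValueError("predictions must align with table rows")
    selected = np.array([p.selected for p in predictions])
    sel_freq = np.bincount(selected, minlength=table.m) / n

    mat = table.metric_matrix("mean_score")
    winners = mat == mat.max(axis=1, keepdims=True)
    oracle_freq = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n

    agree_flags = [bool(winners[i, selected[i]]) for i in range(n)]

    order = np.lexsort((np.arange(table.m), -sel_freq))
    top_solvers = [int(i) for i in order[:top]]
    per_solver = []
    for j in top_solvers:
        per_solver.append({
            "solver": table.portfolio.solver_ids[j],
            "solver_index": j,
            "selector_frequency": float(sel_freq[j]),
            "oracle_frequency": float(oracle_freq[j]),
            "relaxed_success_rate": float(table.success_relaxed[:, j].mean()),
        })
    return {
        "top_solvers": per_solver,
        "selector_frequencies": sel_freq,
        "oracle_frequencies": oracle_freq,
        "oracle_agreement_flags": agree_flags,
        "oracle_agreement_rate": float(np.mean(agree_flags)),
    }


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Success rates, gap closures and a paired-test p-value for one evaluation."""

    sbs_rate: dict = field(default_factory=dict)          # criterion -> %
    selector_rate: dict = field(default_factory=dict)
    vbs_rate: dict = field(default_factory=dict)
    gap_closed_percent: dict = field(default_factory=dict)
    p_value: float = 1.0
    selection_frequencies: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "sbs_rate": self.sbs_rate,
            "selector_rate": self.selector_rate,
            "vbs_rate": self.vbs_rate,
            "gap_closed_percent": self.gap_closed_percent,
            "p_value": self.p_value,
        }
        if self.selection_frequencies is not None:
            out["selection_frequencies"] = list(map(float, self.selection_frequencies))
        return out


def evaluate(selections, table: PerformanceTable) -> EvalReport:
    """Assemble the standard report for a vector of per-instance selections.

    ``selections`` maps each table row to a chosen solver index (a selector's
    argmax output, the SBS constant, or the oracle).  Rates are percentages.
    """
    sel = np.asarray(selections, dtype=int)
    if sel.shape != (table.n,):
        raise ValueError("selections must provide one solver index per table row")
    from .objectives import paired_test

    report = EvalReport()
    rows = np.arange(table.n)
    for criterion in ("strict", "relaxed"):
        mat = table.metric_matrix(criterion)
        sbs_idx = sbs(table, criterion)
        sbs_perf = float(mat[:, sbs_idx].mean())
        vbs_perf = float(mat.max(axis=1).mean())
        as_perf = float(mat[rows, sel].mean())
        report.sbs_rate[criterion] = 100 * sbs_perf
        report.selector_rate[criterion] = 100 * as_perf
        report.vbs_rate[criterion] = 100 * vbs_perf
        if vbs_perf == sbs_perf:
            report.gap_closed_percent[criterion] = float("nan")
            warnings.warn(f"VBS == SBS under {criterion} criterion; gap closure NA",
                          stacklevel=2)
        else:
            report.gap_closed_percent[criterion] = gap_closed(as_perf, sbs_perf, vbs_perf)
    relaxed = table.metric_matrix("relaxed")
    sbs_relaxed = sbs(table, "relaxed")
    report.p_value = paired_test(relaxed[rows, sel].astype(int),
                                 relaxed[:, sbs_relaxed].astype(int))
    report.selection_frequencies = np.bincount(sel, minlength=table.m) / table.n
    return report


def evaluate_cross_benchmark(selections, train_table: PerformanceTable,
                             test_table: PerformanceTable) -> EvalReport:
    """Cross-benchmark evaluation; portfolios must match exactly."""
    if train_table.portfolio.solver_ids != test_table.portfolio.solver_ids:
        raise ValueError("cross-benchmark evaluation requires identical solver portfolios")
    return evaluate(selections, test_table)
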