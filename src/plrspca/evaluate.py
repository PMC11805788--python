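"""Selection-quality metrics and the Monte-Carlo experiment driver.

Given a ground-truth set of important pairwise logratios (from the
simulator) and a selection produced by the sparse-PCA path, this module
computes false positive / false negative rates, capture curves (fraction of
important PLRs found among the first r chosen), cumulative-rank differences
against the ideal variance ordering, and a greedy stepwise baseline (STEP)
that orders non-collinear logratios by explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coda import PlrMatrix, center_columns, plr_matrix, plr_variance_ranks
from .simulate import ScenarioDataset, ScenarioSpec, simulate_scenario
from .spca import SpcaConfig, adjusted_explained_variance, fit_spca
from .stability import (
    AlphaGrid,
    StabilityPaths,
    find_alpha_max,
    make_alpha_grid,
    stability_order,
    stability_paths,
)

__all__ = [
    "ConfusionRates",
    "confusion_rates",
    "capture_curve",
    "rank_difference_curve",
    "step_select",
    "half_sparsity_index",
    "ScenarioRun",
    "run_scenario_analysis",
    "scenario_experiment",
    "compare_with_step",
]


# ---------------------------------------------------------------------------
# Confusion rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionRates:
    """Counts and rates of a selection against ground truth.

    fpr = fp / (fp + tn): fraction of truly unimportant PLRs selected.
    fnr = fn / (fn + tp): fraction of truly important PLRs missed.
    Empty denominators yield 0 (with a warning).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def fpr(self) -> float:
        if self.fp + self.tn == 0:
            warnings.warn("no unimportant PLRs; FPR defined as 0", stacklevel=2)
            return 0.0
        return self.fp / (self.fp + self.tn)

    @property
    def fnr(self) -> float:
        if self.fn + self.tp == 0:
            warnings.warn("no important PLRs; FNR defined as 0", stacklevel=2)
            return 0.0
        return self.fn / (self.fn + self.tp)


def confusion_rates(selected, important, pairs) -> ConfusionRates:
    """Count TP/FP/TN/FN of ``selected`` against ``important`` over ``pairs``."""
    selected = set(selected)
    important = set(important)
    universe = set(pairs)
    if not selected <= universe or not important <= universe:
        raise ValueError("selected and important must be subsets of the pair universe")
    tp = len(selected & important)
    fp = len(selected - important)
    fn = len(important - selected)
    tn = len(universe) - tp - fp - fn
    return ConfusionRates(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# Ordering-quality curves
# ---------------------------------------------------------------------------


def capture_curve(ordered_plrs, important, r_max: int) -> np.ndarray:
    """Percentage of important PLRs found among the first r, r = 1..r_max.

    Orderings shorter than r_max are padded implicitly: entries beyond the
    list length capture nothing further.
    """
    important = set(important)
    if not important:
        raise ValueError("important set is empty")
    hits = 0
    out = np.zeros(r_max)
    for r in range(r_max):
        if r < len(ordered_plrs) and tuple(ordered_plrs[r]) in important:
            hits += 1
        out[r] = 100.0 * hits / len(important)
    return out


def rank_difference_curve(ordered_plrs, ranks, r_max: int) -> np.ndarray:
    """Cumulative rank of the first r chosen PLRs minus the ideal r(r+1)/2.

    ``ranks`` maps each PLR to its variance rank (1 = highest variance).
    Zero means the ordering follows the variance ranking exactly; the
    difference is nonnegative because any r distinct ranks sum to at least
    1 + ... + r.
    """
    chosen = [tuple(p) for p in ordered_plrs[:r_max]]
    if len(set(chosen)) != len(chosen):
        raise ValueError("ordered_plrs contains duplicates")
    if len(chosen) < r_max:
        raise ValueError(f"need at least r_max={r_max} ordered PLRs, got {len(chosen)}")
    cum = np.cumsum([ranks[p] for p in chosen])
    ideal = np.arange(1, r_max + 1).cumsum()
    return (cum - ideal).astype(float)


def ranks_by_pair(x: PlrMatrix) -> dict[tuple[str, str], int]:
    """Variance ranks of a centred PLR matrix keyed by pair."""
    return dict(zip(x.pairs, (int(r) for r in plr_variance_ranks(x))))


# ---------------------------------------------------------------------------
# STEP baseline: greedy forward selection of non-collinear logratios
# ---------------------------------------------------------------------------


def step_select(x: PlrMatrix, max_ratios: int | None = None) -> list[tuple[str, str]]:
    """Greedy stepwise logratio selection ordered by explained variance.

    At each step the candidate logratio maximising the cumulative R^2 of the
    least-squares reconstruction of the whole centred PLR matrix from the
    chosen columns is added.  Candidates that would close a cycle in the
    graph of parts already linked by chosen ratios are excluded (such a
    logratio is an exact linear combination of earlier ones: choosing
    ln(x_i/x_j) and ln(x_j/x_k) rules out ln(x_i/x_k)), so the chosen edges
    always form a forest and at most D-1 ratios are returned.
    """
    if not x.centered:
        raise ValueError("step_select expects a centred PlrMatrix")
    X = x.values
    parts = sorted({p for pair in x.pairs for p in pair})
    D = len(parts)
    part_idx = {p: i for i, p in enumerate(parts)}
    limit = D - 1 if max_ratios is None else min(max_ratios, D - 1)

    # union-find over parts
    parent = list(range(D))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    chosen: list[tuple[str, str]] = []
    Q = np.empty((X.shape[0], 0))  # orthonormal basis of the chosen span
    for _ in range(limit):
        best_gain, best_p, best_q = -1.0, None, None
        for p, pair in enumerate(x.pairs):
            if pair in chosen:
                continue
            ra, rb = find(part_idx[pair[0]]), find(part_idx[pair[1]])
            if ra == rb:
                continue  # collinear with already-chosen ratios
            q = X[:, p] - Q @ (Q.T @ X[:, p])
            nq = np.linalg.norm(q)
            if nq <= 1e-10 * max(np.linalg.norm(X[:, p]), 1.0):
                continue
            q = q / nq
            gain = float(np.sum((q @ X) ** 2))
            if gain > best_gain:
                best_gain, best_p, best_q = gain, p, q
        if best_p is None:
            break
        pair = x.pairs[best_p]
        chosen.append(pair)
        parent[find(part_idx[pair[0]])] = find(part_idx[pair[1]])
        Q = np.column_stack([Q, best_q])
    return chosen


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def half_sparsity_index(zero_proportion: np.ndarray, rule: str = "first_exceeds") -> int:
    """Grid index of the 'roughly half of the logratios are zero' model.

    ``first_exceeds``: first grid point with zero proportion > 0.5 (falls
    back to the last point if sparsity never crosses one half).
    ``closest``: grid point with zero proportion closest to 0.5 (first such
    on ties).
    """
    zp = np.asarray(zero_proportion)
    if rule == "first_exceeds":
        above = np.flatnonzero(zp > 0.5)
        return int(above[0]) if above.size else len(zp) - 1
    if rule == "closest":
        return int(np.argmin(np.abs(zp - 0.5)))
    raise ValueError(f"unknown half-sparsity rule {rule!r}")


@dataclass(frozen=True)
class ScenarioRun:
    """Everything measured on one simulated dataset."""

    dataset: ScenarioDataset
    x: PlrMatrix
    paths: StabilityPaths
    grid: AlphaGrid
    fpr: np.ndarray
    fnr: np.ndarray
    half_index: int

    @property
    def dense_exvar(self) -> float:
        return float(self.paths.grid_exvar[0])

    @property
    def half_exvar(self) -> float:
        return float(self.paths.grid_exvar[self.half_index])

    @property
    def half_fpr(self) -> float:
        return float(self.fpr[self.half_index])

    @property
    def half_fnr(self) -> float:
        return float(self.fnr[self.half_index])


def run_scenario_analysis(
    spec: ScenarioSpec,
    *,
    k: int = 2,
    beta: float = 1e-4,
    grid_size: int = 51,
    half_rule: str = "first_exceeds",
    dense_only: bool = False,
) -> ScenarioRun:
    """Simulate one dataset and run the full sparsity-path analysis on it.

    ``dense_only=True`` fits just the alpha=0 model (grid of the requested
    size with empty selection bookkeeping is skipped) — used when only the
    dense explained variability is needed.
    """
    dataset = simulate_scenario(spec)
    x = center_columns(plr_matrix(dataset.table))
    config = SpcaConfig(alpha=0.0, beta=beta, k=k)
    if dense_only:
        fit = fit_spca(x, config)
        exvar = adjusted_explained_variance(x, fit)
        grid = AlphaGrid(np.array([0.0, 1.0]), 1.0)
        P = x.P
        paths = StabilityPaths(
            selection=np.ones((P, 2), dtype=int),
            totals=np.full(P, 2),
            exvar=np.zeros(P),
            order=np.arange(P),
            grid=grid,
            pairs=x.pairs,
            grid_exvar=np.array([exvar, exvar]),
        )
        return ScenarioRun(dataset, x, paths, grid, np.zeros(2), np.zeros(2), 0)

    alpha_max = find_alpha_max(x, config)
    grid = make_alpha_grid(alpha_max, grid_size)
    paths = stability_paths(x, grid, config)

    important = dataset.important_plrs
    pair_arr = np.array([p in important for p in x.pairs])
    n_imp = int(pair_arr.sum())
    n_unimp = x.P - n_imp
    sel = paths.selection.astype(bool)
    tp = sel[pair_arr].sum(axis=0)
    fp = sel[~pair_arr].sum(axis=0)
    fpr = fp / n_unimp if n_unimp else np.zeros(sel.shape[1])
    fnr = (n_imp - tp) / n_imp if n_imp else np.zeros(sel.shape[1])
    half = half_sparsity_index(paths.zero_proportion, half_rule)
    return ScenarioRun(dataset, x, paths, grid, fpr, fnr, half)


def scenario_experiment(
    scenario: str,
    D: int = 10,
    *,
    n_runs: int = 100,
    n: int = 100,
    seed: int = 1,
    k: int = 2,
    beta: float = 1e-4,
    grid_size: int = 51,
    half_rule: str = "first_exceeds",
    dense_only: bool = False,
) -> dict:
    """Monte-Carlo summary over repeated simulated datasets.

    Returns mean dense explained variability and, unless ``dense_only``,
    the mean explained variability, FPR, FNR and zero proportion at the
    half-sparsity model, plus the per-run values.
    """
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    dense, half_ev, half_fpr, half_fnr, half_zero = [], [], [], [], []
    for s in run_seeds:
        spec = ScenarioSpec(scenario=scenario, D=D, n=n, seed=int(s))
        run = run_scenario_analysis(
            spec, k=k, beta=beta, grid_size=grid_size, half_rule=half_rule,
            dense_only=dense_only,
        )
        dense.append(run.dense_exvar)
        if not dense_only:
            half_ev.append(run.half_exvar)
            half_fpr.append(run.half_fpr)
            half_fnr.append(run.half_fnr)
            half_zero.append(float(run.paths.zero_proportion[run.half_index]))
    out = {
        "scenario": scenario,
        "D": D,
        "n_runs": n_runs,
        "mean_dense_exvar": float(np.mean(dense)),
        "dense_exvar": np.asarray(dense),
    }
    if not dense_only:
        out.update(
            mean_half_exvar=float(np.mean(half_ev)),
            mean_half_fpr=float(np.mean(half_fpr)),
            mean_half_fnr=float(np.mean(half_fnr)),
            mean_half_zero_proportion=float(np.mean(half_zero)),
            half_exvar=np.asarray(half_ev),
            half_fpr=np.asarray(half_fpr),
            half_fnr=np.asarray(half_fnr),
        )
    return out


def compare_with_step(
    scenario: str,
    D: int = 10,
    *,
    n_runs: int = 10,
    n: int = 100,
    seed: int = 1,
    k: int = 2,
    beta: float = 1e-4,
    grid_size: int = 51,
) -> dict:
    """Capture curves and cumulative-rank differences: sparse PCA vs STEP.

    For each run the D-1 most stable PLRs (sparse PCA) and the D-1 STEP
    ratios are scored against the ground-truth important set and against the
    ideal variance ordering; curves are averaged across runs.
    """
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    r_max = D - 1
    cap_spca, cap_step, rank_spca, rank_step = [], [], [], []
    for s in run_seeds:
        spec = ScenarioSpec(scenario=scenario, D=D, n=n, seed=int(s))
        run = run_scenario_analysis(spec, k=k, beta=beta, grid_size=grid_size)
        ordered = stability_order(run.paths)[:r_max]
        stepped = step_select(run.x, r_max)
        important = run.dataset.important_plrs
        ranks = ranks_by_pair(run.x)
        cap_spca.append(capture_curve(ordered, important, r_max))
        cap_step.append(capture_curve(stepped, important, r_max))
        rank_spca.append(rank_difference_curve(ordered, ranks, r_max))
        rank_step.append(rank_difference_curve(stepped, ranks, min(r_max, len(stepped))))
    return {
        "capture_spca": np.mean(cap_spca, axis=0),
        "capture_step": np.mean(cap_step, axis=0),
        "rank_diff_spca": np.mean(rank_spca, axis=0),
        "rank_diff_step": np.mean(rank_step, axis=0),
    }
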