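"""Sparsity-path machinery: alpha_max search, the 51-point grid, stability
paths, stability ordering and per-logratio explained variability.

A pairwise logratio is "stable" when it keeps a nonzero loading as the
sparsity weight alpha grows.  We fit sparse PCA on a grid from the dense
model (alpha=0) to full sparsity (alpha_max, the smallest weight wiping out
every loading), record the binary selection matrix, and order logratios by
the number of grid points at which they are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import PlrMatrix, pair_label, total_variance
from .spca import SpcaConfig, SpcaFit, fit_spca, adjusted_explained_variance

__all__ = [
    "AlphaGrid",
    "StabilityPaths",
    "find_alpha_max",
    "make_alpha_grid",
    "stability_paths",
    "stability_order",
    "exvar_per_plr",
    "part_occurrence_counts",
    "paths_to_frame",
]

GRID_SIZE = 51
# interior grid spans [alpha_max * GRID_FLOOR, alpha_max]; 0 is prepended
GRID_FLOOR = 1e-4


@dataclass(frozen=True)
class AlphaGrid:
    """Ordered sparsity weights: 0, then log-spaced up to alpha_max."""

    values: np.ndarray
    alpha_max: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v[0] != 0.0 or v[-1] != self.alpha_max or np.any(np.diff(v) <= 0):
            raise ValueError("grid must start at 0, end at alpha_max, strictly increase")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class StabilityPaths:
    """Selection paths of every PLR across the alpha grid.

    ``selection[p, g]`` is 1 when PLR p has a nonzero loading at grid point g;
    ``totals`` are row sums; ``exvar`` is the per-PLR explained variability
    (percent); ``order`` sorts PLRs by (totals desc, exvar desc, pair label);
    ``grid_exvar`` is the model-level explained variability at each grid
    point (the red curve of the sparsity/variability trade-off plot).
    """

    selection: np.ndarray
    totals: np.ndarray
    exvar: np.ndarray
    order: np.ndarray
    grid: AlphaGrid
    pairs: tuple[tuple[str, str], ...]
    grid_exvar: np.ndarray

    @property
    def P(self) -> int:
        return self.selection.shape[0]

    @property
    def zero_proportion(self) -> np.ndarray:
        """Fraction of PLRs with zero loadings at each grid point."""
        return 1.0 - self.selection.mean(axis=0)


def find_alpha_max(x: PlrMatrix, config: SpcaConfig) -> float:
    """Smallest (to within 5% relative width) alpha with an all-zero fit.

    Brackets by doubling from a spectral starting guess, then bisects until
    upper/lower <= 1.05.  The returned value satisfies: fit(alpha) has B = 0
    and fit(alpha/2) has B != 0.
    """
    X = x.values
    if np.all(X == 0.0):
        raise ValueError("cannot search alpha_max on an all-zero matrix")

    def is_zero(alpha: float) -> bool:
        cfg = SpcaConfig(
            alpha=alpha, beta=config.beta, k=config.k, max_iter=config.max_iter, tol=config.tol
        )
        return not np.any(fit_spca(x, cfg).B != 0.0)

    # spectral guess near the scale that kills the leading loading vector
    s1 = np.linalg.norm(X, 2)
    hi = s1**2 * 0.1
    for _ in range(60):
        if is_zero(hi):
            break
        hi *= 2.0
    else:  # pragma: no cover - pathological scaling
        raise RuntimeError("alpha_max bracketing failed to find an all-zero fit")
    lo = hi / 2.0
    while is_zero(lo):
        hi = lo
        lo /= 2.0
        if lo < 1e3 * np.finfo(float).tiny:  # pragma: no cover
            raise RuntimeError("alpha_max bracketing collapsed toward zero")
    while hi / lo > 1.05:
        mid = np.sqrt(lo * hi)
        if is_zero(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def make_alpha_grid(alpha_max: float, size: int = GRID_SIZE) -> AlphaGrid:
    """0 followed by ``size - 1`` log-spaced values up to alpha_max."""
    if alpha_max <= 0:
        raise ValueError("alpha_max must be positive")
    if size < 2:
        raise ValueError("grid needs at least 2 points")
    interior = np.geomspace(alpha_max * GRID_FLOOR, alpha_max, size - 1)
    interior[-1] = alpha_max  # exact endpoint despite float rounding
    return AlphaGrid(np.concatenate(([0.0], interior)), alpha_max)


def stability_paths(
    x: PlrMatrix,
    grid: AlphaGrid,
    config: SpcaConfig,
    *,
    warm_start: bool = True,
    exvar_mode: str = "reconstruction",
) -> StabilityPaths:
    """Fit sparse PCA at every grid point and collect selection paths.

    Fits are warm-started from the previous (smaller-alpha) solution by
    default, which stabilises the paths; ``warm_start=False`` cold-starts
    every fit from the spectral initialisation.  The final grid point is
    always verified to be fully sparse (it is refit cold if a warm start
    left stray loadings).
    """
    P = x.P
    G = len(grid)
    selection = np.zeros((P, G), dtype=int)
    grid_exvar = np.zeros(G)
    init = None
    for g, alpha in enumerate(grid.values):
        cfg = SpcaConfig(
            alpha=float(alpha),
            beta=config.beta,
            k=config.k,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        fit = fit_spca(x, cfg, init=init)
        if g == G - 1 and fit.n_selected > 0 and warm_start:
            fit = fit_spca(x, cfg)  # cold restart at alpha_max
        selection[:, g] = np.any(fit.B != 0.0, axis=1).astype(int)
        grid_exvar[g] = adjusted_explained_variance(x, fit)
        if warm_start:
            init = (fit.B, fit.H)
    totals = selection.sum(axis=1)
    exvar = exvar_per_plr(x, mode=exvar_mode)
    order = _stability_argsort(totals, exvar, x.pairs)
    return StabilityPaths(
        selection=selection,
        totals=totals,
        exvar=exvar,
        order=order,
        grid=grid,
        pairs=x.pairs,
        grid_exvar=grid_exvar,
    )


def _stability_argsort(totals, exvar, pairs) -> np.ndarray:
    idx = np.arange(len(totals))
    return np.array(
        sorted(idx, key=lambda p: (-totals[p], -exvar[p], pairs[p])), dtype=int
    )


def stability_order(paths: StabilityPaths) -> list[tuple[str, str]]:
    """PLRs sorted by selection count (desc), then exvar (desc), then label."""
    return [paths.pairs[p] for p in paths.order]


def exvar_per_plr(x: PlrMatrix, mode: str = "reconstruction") -> np.ndarray:
    """Percentage of total variability explained by each single logratio.

    ``mode="reconstruction"`` (default): R^2 of the rank-1 least-squares
    reconstruction of the whole centred PLR matrix from the one column, i.e.
    100 * sum_m cov(x_p, x_m)^2 / (var(x_p) * sum_m var(x_m)).  A logratio
    close to the dominant axis of variation scores high even if its own
    variance is modest.

    ``mode="variance"``: the column's own share, 100 * var(x_p) / total.
    """
    X = x.values
    if not x.centered:
        raise ValueError("exvar_per_plr expects a centred PlrMatrix")
    if x.n < 3:
        raise ValueError("exvar_per_plr needs n >= 3")
    col_ss = np.sum(X**2, axis=0)  # (n-1) * var per column
    tot_ss = float(col_ss.sum())
    if mode == "variance":
        return 100.0 * col_ss / tot_ss
    if mode != "reconstruction":
        raise ValueError(f"unknown exvar mode {mode!r}")
    out = np.zeros(x.P)
    zero_var = col_ss <= 0
    if np.any(zero_var):
        warnings.warn("zero-variance PLR column(s); their exvar is set to 0", stacklevel=2)
    cross = X.T @ X  # cross[p, m] = (n-1) * cov(x_p, x_m)
    ok = ~zero_var
    out[ok] = 100.0 * np.sum(cross[ok] ** 2, axis=1) / (col_ss[ok] * tot_ss)
    return out


def part_occurrence_counts(paths: StabilityPaths, part_names) -> np.ndarray:
    """D x G matrix: how many selected PLRs at grid point g contain part d.

    Column sums equal twice the number of selected PLRs (each names 2 parts).
    """
    part_index = {name: d for d, name in enumerate(part_names)}
    counts = np.zeros((len(part_names), paths.selection.shape[1]), dtype=int)
    for p, (a, b) in enumerate(paths.pairs):
        counts[part_index[a]] += paths.selection[p]
        counts[part_index[b]] += paths.selection[p]
    return counts


def paths_to_frame(paths: StabilityPaths) -> pd.DataFrame:
    """Stability paths as a table: rows in stability order, one column per
    alpha value, then 'total' and 'exvar' (the stability-heatmap layout)."""
    rows = paths.order
    df = pd.DataFrame(
        paths.selection[rows],
        index=[pair_label(*paths.pairs[p]) for p in rows],
        columns=[f"{a:.6g}" for a in paths.grid.values],
    )
    df["total"] = paths.totals[rows]
    df["exvar"] = np.round(paths.exvar[rows], 2)
    return df
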