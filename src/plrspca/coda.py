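"""Compositional-data primitives.

A composition is a vector of strictly positive parts carrying only relative
information: any positive rescaling of a sample is the same datum (scale
invariance).  All statistics here therefore operate on logratios.  The module
provides closure, the full matrix of pairwise logratios ln(x_i/x_j), centred
logratios (clr), sequential-binary-partition (SBP) contrast matrices and the
balance back-transform, plus the variance bookkeeping the selection pipeline
relies on.

Conventions
-----------
* Pairs are ordered lexicographically with numerator index < denominator
  index: (1,2), (1,3), ..., (D-1,D).  A D-part composition yields
  P = D(D-1)/2 stored pairwise logratios (the remaining D(D-1)/2 differ only
  by sign).
* Column centering uses the arithmetic mean; variances use denominator n-1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "PlrMatrix",
    "SbpScheme",
    "ContrastMatrix",
    "close",
    "plr_matrix",
    "center_columns",
    "clr_matrix",
    "contrast_from_sbp",
    "balances_to_composition",
    "total_variance",
    "plr_variance_ranks",
    "pair_label",
    "all_pairs",
    "read_composition_csv",
    "write_composition_csv",
    "write_plr_csv",
    "read_sbp_csv",
    "write_sbp_csv",
]


def pair_label(num: str, den: str) -> str:
    """Canonical label for the pairwise logratio ln(num/den)."""
    return f"ln({num}/{den})"


def all_pairs(part_names: "list[str] | tuple[str, ...]") -> list[tuple[str, str]]:
    """All unordered part pairs in lexicographic index order, numerator first."""
    names = list(part_names)
    return [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionTable:
    """n x D matrix of strictly positive parts with part names and sample ids.

    Rows are scale-equivalent samples; the absolute row sums carry no
    information.  D >= 3 is required (with two parts there is a single
    logratio and nothing to select).
    """

    values: np.ndarray
    part_names: tuple[str, ...]
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("composition values must be a 2-d matrix")
        n, D = values.shape
        if D < 3:
            raise ValueError(f"a composition needs at least 3 parts, got D={D}")
        if len(self.part_names) != D:
            raise ValueError("part_names length must match the number of columns")
        if len(set(self.part_names)) != D:
            raise ValueError("part_names must be unique")
        object.__setattr__(self, "part_names", tuple(self.part_names))
        if not self.sample_ids:
            object.__setattr__(self, "sample_ids", tuple(f"s{i + 1}" for i in range(n)))
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match the number of rows")
        else:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if not np.all(np.isfinite(values)):
            raise ValueError("composition contains non-finite entries")
        if np.any(values <= 0):
            r, c = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"nonpositive entry at sample {self.sample_ids[r]!r}, "
                f"part {self.part_names[c]!r}: {values[r, c]}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PlrMatrix:
    """n x P matrix of pairwise logratios with pair labels.

    ``pairs[p] = (num, den)`` means column p is ln(num/den), numerator having
    the lower part index.  ``centered`` records whether columns have been
    mean-centred (the state sparse PCA consumes).
    """

    values: np.ndarray
    pairs: tuple[tuple[str, str], ...]
    centered: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        if values.ndim != 2 or values.shape[1] != len(self.pairs):
            raise ValueError("values/pairs shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def P(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        return [pair_label(a, b) for a, b in self.pairs]


@dataclass(frozen=True)
class SbpScheme:
    """Sequential binary partition encoded as a D x (D-1) sign matrix.

    Column k holds +1 for parts in the numerator group of balance k, -1 for
    the denominator group and 0 for parts not involved.  A valid scheme
    corresponds to a full binary tree over the parts: the support of every
    balance is recursively split until single parts remain.  Validation is by
    tree reconstruction and is order-agnostic (the balances may be listed in
    any order).
    """

    signs: np.ndarray
    part_names: tuple[str, ...]
    balance_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        signs = np.asarray(self.signs, dtype=int)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "part_names", tuple(self.part_names))
        D = len(self.part_names)
        if signs.shape != (D, D - 1):
            raise ValueError(f"sign matrix must be D x (D-1) = {D} x {D - 1}, got {signs.shape}")
        if not np.all(np.isin(signs, (-1, 0, 1))):
            raise ValueError("sign matrix entries must be in {-1, 0, +1}")
        if not self.balance_names:
            object.__setattr__(
                self, "balance_names", tuple(f"b{k + 1}" for k in range(D - 1))
            )
        elif len(self.balance_names) != D - 1:
            raise ValueError("balance_names length must be D-1")
        else:
            object.__setattr__(self, "balance_names", tuple(self.balance_names))
        self._validate_tree()

    @property
    def D(self) -> int:
        return len(self.part_names)

    def _validate_tree(self) -> None:
        """Check that the columns form a nested (laminar) binary partition."""
        D = self.D
        groups: dict[frozenset[int], int] = {}
        for k in range(D - 1):
            col = self.signs[:, k]
            pos = frozenset(np.flatnonzero(col > 0).tolist())
            neg = frozenset(np.flatnonzero(col < 0).tolist())
            if not pos or not neg:
                raise ValueError(
                    f"balance {self.balance_names[k]!r} needs at least one '+' and one '-' part"
                )
            support = pos | neg
            if support in groups:
                raise ValueError(
                    f"balances {self.balance_names[groups[support]]!r} and "
                    f"{self.balance_names[k]!r} split the same part group twice"
                )
            groups[support] = k
        # Tree reconstruction: the full part set must be split, and every
        # multi-part group produced by a split must itself be split.
        root = frozenset(range(D))
        if root not in groups:
            raise ValueError("no balance splits the full part set (missing root split)")
        pending = [root]
        seen: set[frozenset[int]] = set()
        while pending:
            grp = pending.pop()
            seen.add(grp)
            k = groups[grp]
            col = self.signs[:, k]
            for sub in (
                frozenset(i for i in grp if col[i] > 0),
                frozenset(i for i in grp if col[i] < 0),
            ):
                if len(sub) == 1:
                    continue
                if sub not in groups:
                    raise ValueError(
                        f"group {sorted(self.part_names[i] for i in sub)} produced by balance "
                        f"{self.balance_names[k]!r} is never split further: not a valid SBP"
                    )
                pending.append(sub)
        if len(seen) != D - 1:
            # Unreached columns split groups that no ancestor produced.
            stray = [self.balance_names[k] for g, k in groups.items() if g not in seen]
            raise ValueError(f"balances {stray} are not nested within the partition tree")


@dataclass(frozen=True)
class ContrastMatrix:
    """(D-1) x D matrix of orthonormal log-contrast (balance) coefficients."""

    coefficients: np.ndarray
    part_names: tuple[str, ...] = ()
    balance_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        V = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", V)
        if V.ndim != 2 or V.shape[0] != V.shape[1] - 1:
            raise ValueError("contrast matrix must be (D-1) x D")
        if not np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-10):
            raise ValueError("contrast rows are not orthonormal")
        if not np.allclose(V.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("contrast rows must sum to zero")

    @property
    def D(self) -> int:
        return self.coefficients.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def close(values, constant: float = 1.0, part_names=None, sample_ids=None) -> CompositionTable:
    """Normalise rows to a constant sum (closure).

    Ratios within each row are unchanged; closure only fixes the arbitrary
    scale of each sample.
    """
    if constant <= 0:
        raise ValueError("closure constant must be positive")
    if isinstance(values, CompositionTable):
        table = values
        values = table.values
        part_names = part_names or table.part_names
        sample_ids = sample_ids or table.sample_ids
    values = np.asarray(values, dtype=float)
    if part_names is None:
        part_names = [f"p{j + 1}" for j in range(values.shape[1])]
    if np.any(values <= 0):
        r, c = np.argwhere(values <= 0)[0]
        raise ValueError(f"nonpositive entry at row {r}, column {c}: {values[r, c]}")
    closed = constant * values / values.sum(axis=1, keepdims=True)
    return CompositionTable(closed, tuple(part_names), tuple(sample_ids or ()))


def plr_matrix(table: CompositionTable) -> PlrMatrix:
    """All D(D-1)/2 pairwise logratios ln(x_i/x_j), i<j, lexicographic order.

    Output is not centred; see :func:`center_columns`.
    """
    logs = np.log(table.values)
    D = table.D
    idx_i, idx_j = np.triu_indices(D, k=1)
    values = logs[:, idx_i] - logs[:, idx_j]
    pairs = [(table.part_names[i], table.part_names[j]) for i, j in zip(idx_i, idx_j)]
    return PlrMatrix(values, tuple(pairs), centered=False)


def center_columns(m: PlrMatrix) -> PlrMatrix:
    """Subtract the arithmetic column means and set the centred flag."""
    return replace(m, values=m.values - m.values.mean(axis=0, keepdims=True), centered=True)


def clr_matrix(table: CompositionTable) -> np.ndarray:
    """Centred logratios: ln(part / geometric mean of the row).  Rows sum to 0."""
    logs = np.log(table.values)
    return logs - logs.mean(axis=1, keepdims=True)


def contrast_from_sbp(scheme: SbpScheme) -> ContrastMatrix:
    """Orthonormal balance coefficients for an SBP.

    Balance k with r numerator parts and s denominator parts gets coefficients
    +sqrt(s/(r(r+s))) on the numerator group and -sqrt(r/(s(r+s))) on the
    denominator group, the standard orthonormal-logratio normalisation.
    """
    D = scheme.D
    V = np.zeros((D - 1, D))
    for k in range(D - 1):
        col = scheme.signs[:, k]
        r = int(np.sum(col > 0))
        s = int(np.sum(col < 0))
        V[k, col > 0] = np.sqrt(s / (r * (r + s)))
        V[k, col < 0] = -np.sqrt(r / (s * (r + s)))
    return ContrastMatrix(V, scheme.part_names, scheme.balance_names)


def composition_to_balances(table: CompositionTable, contrast: ContrastMatrix) -> np.ndarray:
    """Forward transform: project clr coordinates onto the contrast rows."""
    return clr_matrix(table) @ contrast.coefficients.T


def balances_to_composition(
    coords: np.ndarray,
    contrast: ContrastMatrix,
    constant: float = 1.0,
    part_names=None,
    sample_ids=None,
) -> CompositionTable:
    """Invert balance coordinates to a closed composition.

    clr = coords @ V (V the contrast matrix), composition = closure(exp(clr)).
    The forward transform of the result reproduces ``coords``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != contrast.coefficients.shape[0]:
        raise ValueError(
            f"coords has {coords.shape[1]} columns, contrast defines "
            f"{contrast.coefficients.shape[0]} balances"
        )
    clr = coords @ contrast.coefficients
    names = part_names or contrast.part_names or None
    return close(np.exp(clr), constant, part_names=names, sample_ids=sample_ids)


def total_variance(m: PlrMatrix) -> float:
    """Sum of column sample variances (denominator n-1) of a centred PLR matrix.

    This is the denominator of every explained-variability percentage.  It is
    invariant to per-sample rescaling of the source composition because
    logratios are.
    """
    if not m.centered:
        raise ValueError("total_variance expects a centred PlrMatrix")
    if m.n < 2:
        raise ValueError("total_variance needs at least 2 samples")
    return float(np.sum(m.values**2) / (m.n - 1))


def plr_variance_ranks(m: PlrMatrix) -> np.ndarray:
    """Rank PLR columns by variance: rank 1 = largest variance.

    Ties are broken by lexicographic pair order (the column order), so the
    output is always a permutation of 1..P.
    """
    if not m.centered:
        raise ValueError("plr_variance_ranks expects a centred PlrMatrix")
    if m.n < 2:
        raise ValueError("plr_variance_ranks needs at least 2 samples")
    variances = np.sum(m.values**2, axis=0) / (m.n - 1)
    # stable argsort on -variance keeps pair order among ties
    order = np.argsort(-variances, kind="stable")
    ranks = np.empty(m.P, dtype=int)
    ranks[order] = np.arange(1, m.P + 1)
    return ranks


# ---------------------------------------------------------------------------
# External interfaces (CSV)
# ---------------------------------------------------------------------------


def read_composition_csv(path, delimiter: str | None = None) -> CompositionTable:
    """Read a composition table: header = part names, first column = sample id.

    The delimiter is sniffed from the header (comma vs tab) unless forced.
    """
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return CompositionTable(
        df.to_numpy(dtype=float),
        tuple(str(c) for c in df.columns),
        tuple(str(i) for i in df.index),
    )


def write_composition_csv(table: CompositionTable, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(table.values, index=list(table.sample_ids), columns=list(table.part_names))
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter)


def write_plr_csv(m: PlrMatrix, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(m.values, columns=m.labels)
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter)


def write_sbp_csv(scheme: SbpScheme, path) -> None:
    """Serialise an SBP as rows = parts, columns = balances, entries in {-1,0,1}."""
    df = pd.DataFrame(
        scheme.signs, index=list(scheme.part_names), columns=list(scheme.balance_names)
    )
    df.index.name = "part"
    df.to_csv(path)


def read_sbp_csv(path) -> SbpScheme:
    df = pd.read_csv(path, index_col=0)
    return SbpScheme(
        df.to_numpy(dtype=int),
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
    )
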