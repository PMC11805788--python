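"""SBP-based scenario generator with known important/unimportant structure.

Data are generated in balance coordinates and back-transformed to a
composition.  "Relevant" balances are jointly Gaussian (unit variances,
equi-correlation rho, default 0.7) and carry the signal; "noise" balances are
iid uniform on (-h, h) (default h=2, variance 4/3).  Sparsity is embedded in
the compositional parts: the parts appearing in relevant balances are the
important ones, and every pairwise logratio within that block is a
ground-truth important PLR.

Scheme construction
-------------------
The sequential binary partition for a scenario with r relevant balances over
D parts is built from two blocks:

* an important block of the first r+1 parts, split by a staircase of r
  relevant balances (part j versus parts j+1..r+1);
* a noise block of the remaining D-r-1 parts, split by a staircase of
  noise balances, preceded by one bridging noise balance contrasting the
  whole important block against the whole noise block (a full SBP over D
  parts needs D-1 balances; the bridge is the one split touching both
  blocks and is drawn from the noise distribution).

Scenario presets (number of relevant balances): A: 5 (D=10) / 10 (D=20),
B: 7 / 15, C: 2 / 4.  Scenario A has a roughly even split of relevant and
noise balances, in B the relevant balances dominate, in C the noise ones do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .coda import (
    CompositionTable,
    ContrastMatrix,
    SbpScheme,
    all_pairs,
    balances_to_composition,
    contrast_from_sbp,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioDataset",
    "default_sbp",
    "default_n_relevant",
    "simulate_scenario",
    "important_plr_set",
]

_N_RELEVANT = {
    ("A", 10): 5,
    ("B", 10): 7,
    ("C", 10): 2,
    ("A", 20): 10,
    ("B", 20): 15,
    ("C", 20): 4,
}


def default_n_relevant(scenario: str, D: int) -> int:
    try:
        return _N_RELEVANT[(scenario.upper(), D)]
    except KeyError:
        raise ValueError(
            f"no preset for scenario {scenario!r} with D={D}; supply an SbpScheme "
            "and n_relevant explicitly"
        ) from None


def _part_names(D: int) -> tuple[str, ...]:
    return tuple(f"x{j + 1:02d}" for j in range(D))


def default_sbp(scenario: str, D: int) -> SbpScheme:
    """Preset SBP for a scenario: relevant staircase over the important block,
    then a bridging noise balance and a staircase over the noise block."""
    r = default_n_relevant(scenario, D)
    return _block_sbp(D, r)


def _block_sbp(D: int, r: int) -> SbpScheme:
    if not 1 <= r <= D - 2:
        raise ValueError(f"need 1 <= n_relevant <= D-2, got {r} with D={D}")
    signs = np.zeros((D, D - 1), dtype=int)
    names = []
    # relevant balances b1..br: staircase over parts 0..r
    for j in range(r):
        signs[j, j] = 1
        signs[j + 1 : r + 1, j] = -1
        names.append(f"b{j + 1}")
    # bridge (first noise balance): important block vs noise block
    signs[: r + 1, r] = 1
    signs[r + 1 :, r] = -1
    names.append(f"b{r + 1}")
    # remaining noise balances: staircase over parts r+1..D-1
    for j in range(D - 2 - r):
        col = r + 1 + j
        signs[r + 1 + j, col] = 1
        signs[r + 2 + j :, col] = -1
        names.append(f"b{col + 1}")
    return SbpScheme(signs, _part_names(D), tuple(names))


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulated scenario.

    ``n_relevant`` is the number of relevant balances (defaults to the
    scenario preset); ``rho`` the equi-correlation of the relevant balances;
    ``noise_half_width`` the half-width h of the U(-h, h) noise balances.
    """

    scenario: str = "A"
    D: int = 10
    n: int = 100
    n_relevant: int | None = None
    rho: float = 0.7
    noise_half_width: float = 2.0
    seed: int = 0
    sbp: SbpScheme | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", self.scenario.upper())
        r = self.n_relevant
        if r is None:
            r = (
                default_n_relevant(self.scenario, self.D)
                if self.sbp is None
                else None
            )
            if r is None:
                raise ValueError("n_relevant must be given with a custom SbpScheme")
            object.__setattr__(self, "n_relevant", r)
        if not 1 <= self.n_relevant <= self.D - 1:
            raise ValueError("need 1 <= n_relevant <= D-1")
        if self.n < 1:
            raise ValueError("n must be positive")
        lo = -1.0 / (self.n_relevant - 1) if self.n_relevant > 1 else -1.0
        if not lo < self.rho < 1.0:
            raise ValueError(
                f"rho={self.rho} outside ({lo:.4g}, 1): correlation matrix not positive definite"
            )
        if self.noise_half_width <= 0:
            raise ValueError("noise_half_width must be positive")

    def scheme(self) -> SbpScheme:
        return self.sbp if self.sbp is not None else _block_sbp(self.D, self.n_relevant)


@dataclass(frozen=True)
class ScenarioDataset:
    """A simulated composition plus its generating scheme and ground truth."""

    table: CompositionTable
    spec: ScenarioSpec
    sbp: SbpScheme
    contrast: ContrastMatrix
    balances: np.ndarray
    relevant_balances: tuple[int, ...]
    important_parts: tuple[str, ...]
    important_plrs: frozenset[tuple[str, str]]

    def ground_truth_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.spec.scenario,
                "D": self.spec.D,
                "n": self.spec.n,
                "n_relevant": self.spec.n_relevant,
                "rho": self.spec.rho,
                "noise_half_width": self.spec.noise_half_width,
                "seed": self.spec.seed,
                "important_parts": list(self.important_parts),
                "important_plrs": sorted(map(list, self.important_plrs)),
            },
            indent=2,
        )


def simulate_scenario(spec: ScenarioSpec) -> ScenarioDataset:
    """Draw balances, back-transform, and attach the ground-truth PLR set.

    The root seed is split into independent streams for the relevant and the
    noise draws, so enlarging the noise block never perturbs the relevant
    coordinates.
    """
    sbp = spec.scheme()
    D, r, n = sbp.D, spec.n_relevant, spec.n
    rel_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng_rel = np.random.default_rng(rel_ss)
    rng_noise = np.random.default_rng(noise_ss)

    cov = np.full((r, r), spec.rho)
    np.fill_diagonal(cov, 1.0)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:  # pragma: no cover - guarded by spec validation
        raise ValueError("relevant-balance covariance is not positive definite") from None
    relevant = rng_rel.standard_normal((n, r)) @ L.T
    h = spec.noise_half_width
    noise = rng_noise.uniform(-h, h, size=(n, D - 1 - r))
    coords = np.concatenate([relevant, noise], axis=1)

    contrast = contrast_from_sbp(sbp)
    table = balances_to_composition(coords, contrast, constant=1.0)

    relevant_idx = tuple(range(r))
    important = _important_parts(sbp, relevant_idx)
    dataset = ScenarioDataset(
        table=table,
        spec=spec,
        sbp=sbp,
        contrast=contrast,
        balances=coords,
        relevant_balances=relevant_idx,
        important_parts=important,
        important_plrs=frozenset(),
    )
    object.__setattr__(dataset, "important_plrs", frozenset(important_plr_set(dataset)))
    return dataset


def _important_parts(sbp: SbpScheme, relevant_idx) -> tuple[str, ...]:
    """Parts carrying a nonzero sign in at least one relevant balance."""
    mask = np.any(sbp.signs[:, list(relevant_idx)] != 0, axis=1)
    return tuple(name for name, m in zip(sbp.part_names, mask) if m)


def important_plr_set(
    dataset: ScenarioDataset, *, include_mixed: bool = False
) -> set[tuple[str, str]]:
    """Ground-truth important PLRs.

    Default rule: every unordered pair with *both* parts in the important
    block.  ``include_mixed=True`` additionally counts pairs of one important
    and one noise part as important (for sensitivity analysis).
    """
    important = set(dataset.important_parts)
    pairs = all_pairs(dataset.table.part_names)
    if include_mixed:
        return {p for p in pairs if p[0] in important or p[1] in important}
    return {p for p in pairs if p[0] in important and p[1] in important}
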