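"""Randomized-rounding post-processing for categorical columns.

The bounded Laplace mechanism releases a continuous value in [-C, C],
but a categorical variable has only ``m`` legal labels; releasing 2.37
for a Glasgow coma "motor" score would leak the fact that perturbation
happened and break downstream consumers.  The fix: place the ``m``
categories on an equally spaced grid

    g_j = -C + 2C * j / (m - 1),   j = 0 .. m-1,

map the perturbed value into index space, ``t = (y + C)(m - 1) / (2C)``
in [0, m-1], and round stochastically between the two adjacent indices
``k = floor(t)`` and ``k + 1`` with Bernoulli probability ``p = t - k``
of rounding up.  The rounding is unbiased (E[index] = t), always lands
on an existing category, and is the identity when the noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CategoricalGrid",
    "IndexPosition",
    "category_grid",
    "to_index_space",
    "randomized_round",
    "discretize_value",
]


@dataclass(frozen=True)
class CategoricalGrid:
    """``m`` equally spaced category anchor points spanning [-C, C]."""

    m: int
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"cardinality m must be >= 2, got {self.m}")
        if not self.C > 0:
            raise ValueError(f"bound C must be positive, got {self.C}")

    @property
    def points(self) -> np.ndarray:
        return -self.C + 2.0 * self.C * np.arange(self.m) / (self.m - 1)

    def encode(self, index) -> np.ndarray:
        """Grid point of category index ``j``."""
        index = np.asarray(index)
        if np.any(index < 0) or np.any(index > self.m - 1):
            raise ValueError(f"category index outside 0..{self.m - 1}")
        return -self.C + 2.0 * self.C * np.asarray(index, dtype=float) / (self.m - 1)

    def decode(self, y) -> np.ndarray:
        """Nearest-grid-point index of a value in [-C, C]."""
        t = (np.asarray(y, dtype=float) + self.C) * (self.m - 1) / (2.0 * self.C)
        return np.clip(np.rint(t).astype(int), 0, self.m - 1)


@dataclass(frozen=True)
class IndexPosition:
    """A position ``t`` in index space split into ``k = floor(t)`` and ``p = t - k``."""

    t: float
    k: int
    p: float


def category_grid(m: int, C: float = 1.0) -> CategoricalGrid:
    """Grid of ``m`` category anchors on [-C, C]."""
    return CategoricalGrid(m=m, C=C)


def _index_parts(y: np.ndarray, grid: CategoricalGrid):
    t = (y + grid.C) * (grid.m - 1) / (2.0 * grid.C)
    # guard float spillover at the top anchor: t = m-1 exactly -> k = m-1, p = 0
    t = np.clip(t, 0.0, grid.m - 1.0)
    k = np.minimum(np.floor(t), grid.m - 2).astype(int) if grid.m > 1 else 0
    # keep k = m-1 (p = 0) at the exact top so the identity holds there too
    k = np.where(t >= grid.m - 1.0, grid.m - 1, k)
    p = t - k
    return t, k, p


def to_index_space(y: float, grid: CategoricalGrid) -> IndexPosition:
    """Affine map of a perturbed value into [0, m-1] index space."""
    y = np.asarray(y, dtype=float)
    if np.any(y < -grid.C) or np.any(y > grid.C):
        raise ValueError(f"value outside [-{grid.C}, {grid.C}]")
    t, k, p = _index_parts(y, grid)
    return IndexPosition(t=float(t), k=int(k), p=float(p))


def randomized_round(pos: IndexPosition, rng: np.random.Generator) -> int:
    """``k + 1`` with probability ``p``, else ``k`` — unbiased in expectation."""
    if not 0.0 <= pos.p < 1.0 + 1e-12:
        raise ValueError(f"invalid Bernoulli probability {pos.p}")
    return int(pos.k) + int(rng.random() < pos.p)


def discretize_value(y, grid: CategoricalGrid, rng: np.random.Generator):
    """Map perturbed values in [-C, C] to category indices (vectorized).

    Composition of the index-space map and the Bernoulli rounding; the
    output is always one of the ``m`` original categories.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < -grid.C) or np.any(y > grid.C):
        raise ValueError(f"value outside [-{grid.C}, {grid.C}]")
    scalar = y.ndim == 0
    t, k, p = _index_parts(np.atleast_1d(y), grid)
    out = k + (rng.random(k.shape) < p)
    return int(out[0]) if scalar else out
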