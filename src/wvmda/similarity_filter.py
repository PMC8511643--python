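"""Adaptive row-wise filtering of an integrated similarity matrix.

Similarity networks carry a long noisy tail: for each entity only the
head of its descending similarity distribution is reliable.  The filter
keeps, per row, the top ``p`` off-diagonal values and zeroes the rest,
where the cut ``p`` adapts to the row's own value distribution:

1.  sort the k - 1 off-diagonal values descending (1-based positions);
2.  the hypothetical position is ``p_h = round(r * k)`` for ratio ``r``
    (default 0.1), clamped into [1, k - 1];
3.  the value at ``p_h`` determines a level bin [lo, lo + 0.1) of width
    0.1 with ``lo = floor(10 v) / 10``;
4.  the leading point ``p_l`` is the position of the value closest to
    the bin's upper edge, the following point ``p_f`` the position of
    the value closest to its lower edge (ties: smallest position);
5.  the final cut is

        p = p_f              if p_f < 2 p_h
        p = p_l              if p_f > 2 p_h and p_l > p_h / 2
        p = 2 p_h            otherwise,

    clamped into [1, k - 1].  Boundary equalities fall through to the
    third branch.

Values before the cut are preserved at their matrix positions; values
after it become 0.  The diagonal entry is never touched.  Because each
row adapts independently the filtered matrix is generally asymmetric;
no re-symmetrisation is applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import SimilarityMatrix

DEFAULT_RATIO = 0.1
LEVEL_WIDTH = 0.1


@dataclass(frozen=True)
class FilterParams:
    """Hypothetical-position ratio r in (0, 1]; bin width is fixed at 0.1."""

    r: float = DEFAULT_RATIO

    def __post_init__(self) -> None:
        if not 0 < self.r <= 1:
            raise ValueError(f"filter ratio must lie in (0, 1], got {self.r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cut_position(sorted_desc: np.ndarray, k: int, r: float) -> int:
    """Final cut position p for a row of length k whose k - 1 off-diagonal
    values are given in descending order."""
    n_off = len(sorted_desc)
    if n_off == 0:
        raise ValueError("empty row")
    p_h = min(max(_round_half_up(r * k), 1), n_off)
    v = float(sorted_desc[p_h - 1])
    lo = math.floor(v * 10 + 1e-9) / 10.0
    hi = lo + LEVEL_WIDTH
    # positions of the values nearest the bin edges; ties -> smallest position
    p_l = int(np.argmin(np.abs(sorted_desc - hi))) + 1
    p_f = int(np.argmin(np.abs(sorted_desc - lo))) + 1
    if p_f < 2 * p_h:
        p = p_f
    elif p_l > p_h / 2:
        p = p_l
    else:
        p = 2 * p_h
    return min(max(p, 1), n_off)


def filter_row(row: np.ndarray, own_index: int, r: float = DEFAULT_RATIO) -> np.ndarray:
    """Filter one similarity row, preserving the entry at ``own_index``.

    Returns a copy where only the row's p largest off-diagonal values
    (ties broken toward smaller matrix positions) survive.
    """
    FilterParams(r)
    row = np.asarray(row, dtype=float)
    k = len(row)
    if k < 2:
        raise ValueError("row must have at least two entries")
    if not 0 <= own_index < k:
        raise IndexError(f"own_index {own_index} out of range for row of length {k}")
    off = np.delete(np.arange(k), own_index)
    vals = row[off]
    # stable descending sort: primary key value desc, secondary matrix index asc
    order = np.lexsort((off, -vals))
    p = cut_position(vals[order], k, r)
    keep = off[order[:p]]
    out = np.zeros_like(row)
    out[keep] = row[keep]
    out[own_index] = row[own_index]
    return out


def filter_matrix(
    sim: SimilarityMatrix, r: float = DEFAULT_RATIO, symmetrize: bool = False
) -> SimilarityMatrix:
    """Filter each row of a similarity matrix independently.

    ``symmetrize=True`` restores symmetry afterwards by taking the
    entrywise maximum with the transpose (off by default: the voting
    stage consumes the asymmetric row-filtered matrix directly).
    """
    values = np.empty_like(sim.values)
    for i in range(sim.k):
        values[i] = filter_row(sim.values[i], i, r)
    if symmetrize:
        values = np.maximum(values, values.T)
    return SimilarityMatrix(list(sim.names), values, kind="filtered")
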