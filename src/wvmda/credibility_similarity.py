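"""Credibility similarity: completing sparse similarity networks from A.

Verified associations are more trustworthy than undetermined ones, so the
binary adjacency matrix A is first recoded into a credibility matrix C:
ones become the credibility ``delta`` (> 1), zeros become a base code
(default -1).  Two miRNAs that respond alike across diseases then have a
large inner product between their credibility rows; the raw inner-product
matrix is rescaled row-wise into [0, 1] and averaged with the externally
supplied functional (miRNA side) or semantic (disease side) similarity.

The raw similarity of rows i and j is

    CM1(i, j) = <C_i, C_j>   (i != j),   CM1(i, i) = 0,

and the rescaling is the symmetric two-row min-max form

    CM(i, j) = (CM1(i,j) - min_i)(CM1(i,j) - min_j)
               / ((max_i - min_i)(max_j - min_j)),

with the row extrema taken after the diagonal is zeroed.  The diagonal of
CM is left at 0; the integration step restores the unit diagonal that the
voting stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, DataFormatError, SimilarityMatrix

DEFAULT_DELTA = 2.0
DEFAULT_BASE_CODE = -1.0


@dataclass
class CredibilityMatrix:
    """Signed recoding of A: delta where A = 1, base code elsewhere."""

    values: np.ndarray
    delta: float
    base_code: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        codes = np.unique(self.values)
        if not np.isin(codes, (self.base_code, self.delta)).all():
            raise ValueError("credibility matrix entries must be base_code or delta")


def build_credibility(
    assoc: AssociationMatrix,
    delta: float = DEFAULT_DELTA,
    base_code: float = DEFAULT_BASE_CODE,
) -> CredibilityMatrix:
    """Recode A elementwise: 1 -> delta, 0 -> base_code; requires delta > 1."""
    if delta <= 1:
        raise ValueError(f"credibility delta must exceed 1, got {delta}")
    values = np.where(assoc.values == 1, delta, base_code)
    return CredibilityMatrix(values, delta=delta, base_code=base_code)


def raw_credibility_similarity(c: np.ndarray) -> np.ndarray:
    """Inner products between all row pairs of C, with a zeroed diagonal.

    Pass ``C`` for the miRNA side or ``C.T`` for the disease side.  The
    diagonal is never used by the voting stage (a voter's self-vote goes
    through the unit diagonal of the integrated matrix instead) and its
    large self products would distort the row-wise rescaling, so it is
    set to 0 up front.
    """
    c = np.asarray(c, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least two rows to compare")
    cm1 = c @ c.T
    np.fill_diagonal(cm1, 0.0)
    return cm1


def scale_credibility(cm1: np.ndarray) -> np.ndarray:
    """Row-wise min-max rescaling of raw credibility similarity into [0, 1].

    Row extrema include the zeroed diagonal.  A constant row carries no
    information; its factor is defined as 0, so any entry touching a
    degenerate row is 0.
    """
    cm1 = np.asarray(cm1, dtype=float)
    if not np.allclose(np.diagonal(cm1), 0.0):
        raise ValueError("diagonal must be zeroed before rescaling")
    rmin = cm1.min(axis=1)
    rmax = cm1.max(axis=1)
    rng = rmax - rmin
    num = (cm1 - rmin[:, None]) * (cm1 - rmin[None, :])
    den = rng[:, None] * rng[None, :]
    out = np.divide(num, den, out=np.zeros_like(cm1), where=den > 0)
    np.fill_diagonal(out, 0.0)
    return out


def credibility_similarity(
    assoc: AssociationMatrix,
    axis: str,
    delta: float = DEFAULT_DELTA,
    base_code: float = DEFAULT_BASE_CODE,
) -> SimilarityMatrix:
    """Full credibility-similarity construction for one axis of A.

    ``axis`` is "mirna" (rows of A, yielding CM) or "disease" (columns,
    yielding CD).
    """
    cred = build_credibility(assoc, delta=delta, base_code=base_code)
    if axis == "mirna":
        c, names = cred.values, assoc.mirna_names
    elif axis == "disease":
        c, names = cred.values.T, assoc.disease_names
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    cm = scale_credibility(raw_credibility_similarity(c))
    return SimilarityMatrix(list(names), cm, kind="credibility")


def integrate(sim_a: SimilarityMatrix, sim_b: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise mean of two similarity matrices with the diagonal forced to 1.

    The unit diagonal guarantees voters absolute status when they vote
    for themselves; the credibility component's diagonal is 0 by
    construction, so it is restored here.
    """
    if sim_a.names != sim_b.names:
        raise DataFormatError("cannot integrate similarity matrices with different axes")
    values = 0.5 * (sim_a.values + sim_b.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(sim_a.names), values, kind="integrated")
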