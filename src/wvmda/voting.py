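"""Weighted voting over the bipartite association network.

Every verified association A(mi, dj) = 1 is a voter; it casts one vote
for every pair in its miRNA row and every pair in its disease column.
A vote received by candidate (mi, dj) from a voter in its row or column
carries the product of three weights:

* basic weight  1 / (N_mi + N_dj - A(mi, dj)) — the reciprocal of the
  number of distinct voters connected to the candidate, so the votes a
  non-voter candidate receives always total exactly 1 and no group of
  voters can dominate by size alone;
* group weight  N^e — a mild boost (default e = 1/3) for candidates
  recommended by larger voter groups, N being the size of the group the
  voter and candidate share (the row count for row votes, the column
  count for column votes);
* candidate weight — the filtered integrated similarity between the
  voter's and the candidate's disease (row votes) or miRNA (column
  votes); the unit diagonal gives voters absolute status on their own
  pair.

The final score accumulates all votes without iteration:

    F(mi, dj) = [ N_mi^e * sum_s D(dj, ds) A(mi, ds)
                + N_dj^e * sum_t M(mi, mt) A(mt, dj) ]
                / (N_mi + N_dj - A(mi, dj)).

A voter's self-vote is counted in both sums.  Candidates connected to no
voter at all (zero denominator) score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, DataFormatError, ScoreMatrix, SimilarityMatrix

DEFAULT_EXPONENT = 1.0 / 3.0


@dataclass(frozen=True)
class VotingParams:
    """Group-weight exponent e >= 0; e = 0 disables the group weight."""

    e: float = DEFAULT_EXPONENT

    def __post_init__(self) -> None:
        if self.e < 0:
            raise ValueError(f"group-weight exponent must be >= 0, got {self.e}")


@dataclass(frozen=True)
class VoterCounts:
    """Per-miRNA (row) and per-disease (column) numbers of voters."""

    n_mirna: np.ndarray
    n_disease: np.ndarray


def voter_counts(assoc: AssociationMatrix) -> VoterCounts:
    """Row and column sums of A: group sizes for the weighting."""
    return VoterCounts(
        n_mirna=assoc.values.sum(axis=1).astype(np.int64),
        n_disease=assoc.values.sum(axis=0).astype(np.int64),
    )


def basic_weight(counts: VoterCounts, assoc: AssociationMatrix, i: int, s: int) -> float:
    """Basic voting weight of any single vote received by candidate (i, s).

    Defined as 1 over the number of voters connected to the candidate,
    counting the candidate's own self-vote once.  An isolated candidate
    (no connected voter) receives no votes; its weight is defined as 0.
    """
    den = counts.n_mirna[i] + counts.n_disease[s] - assoc.values[i, s]
    if den <= 0:
        return 0.0
    return 1.0 / float(den)


def group_weight(group_size: int, e: float = DEFAULT_EXPONENT) -> float:
    """Group influence N^e, with 0^e defined as 0 (an empty group has no voice)."""
    VotingParams(e)
    if group_size < 0:
        raise ValueError("group size must be nonnegative")
    if group_size == 0:
        return 0.0
    return float(group_size) ** e


def score(
    assoc: AssociationMatrix,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    e: float = DEFAULT_EXPONENT,
) -> ScoreMatrix:
    """Final weighted-voting score matrix F.

    ``mirna_sim`` and ``disease_sim`` are the filtered integrated
    similarities M and D; their diagonals must be 1 so that voters keep
    their absolute status.
    """
    VotingParams(e)
    if mirna_sim.names != assoc.mirna_names:
        raise DataFormatError("miRNA similarity axis does not match the association matrix")
    if disease_sim.names != assoc.disease_names:
        raise DataFormatError("disease similarity axis does not match the association matrix")
    a = assoc.values.astype(float)
    counts = voter_counts(assoc)
    n_m = counts.n_mirna.astype(float)
    n_d = counts.n_disease.astype(float)
    g_m = np.where(counts.n_mirna > 0, n_m, 1.0) ** e * (counts.n_mirna > 0)
    g_d = np.where(counts.n_disease > 0, n_d, 1.0) ** e * (counts.n_disease > 0)
    # row votes: sum_s D(dj, ds) A(mi, ds);  column votes: sum_t M(mi, mt) A(mt, dj)
    row_votes = a @ disease_sim.values.T
    col_votes = mirna_sim.values @ a
    raw = g_m[:, None] * row_votes + g_d[None, :] * col_votes
    den = n_m[:, None] + n_d[None, :] - a
    values = np.divide(raw, den, out=np.zeros_like(raw), where=den > 0)
    return ScoreMatrix(list(assoc.mirna_names), list(assoc.disease_names), values)
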