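"""Readers and writers for the external representations used by the pipeline.

Three kinds of delimited text files are supported:

* association edge lists — two columns (miRNA, disease), one verified
  association per row;
* square similarity matrices — header row plus first-column labels;
* ontology inputs — a (child, parent) term edge list together with a
  (disease, term) mapping.

Predicted scores are exported as a four-column ranked table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-8


class DataFormatError(ValueError):
    """An input file violates the expected tabular contract."""


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(names) == 0:
        raise DataFormatError(f"{what}: at least one label required")
    if len(set(names)) != len(names):
        raise DataFormatError(f"{what}: labels must be unique")


@dataclass
class AssociationMatrix:
    """Binary n x m adjacency matrix A over named miRNAs and diseases.

    ``values[i, j] == 1`` records an experimentally verified association
    between miRNA ``mirna_names[i]`` and disease ``disease_names[j]``;
    0 marks an undetermined pair.  The axis orders fixed here are the
    canonical orders for every downstream matrix.
    """

    mirna_names: list[str]
    disease_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.mirna_names, "miRNA axis")
        _check_unique(self.disease_names, "disease axis")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mirna_names), len(self.disease_names)):
            raise DataFormatError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_names)} miRNAs x {len(self.disease_names)} diseases"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise DataFormatError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n(self) -> int:
        return len(self.mirna_names)

    @property
    def m(self) -> int:
        return len(self.disease_names)

    @property
    def size(self) -> int:
        """Total number of miRNA-disease pairs (n * m)."""
        return self.n * self.m

    @property
    def n_known(self) -> int:
        """Number of verified associations (ones in A)."""
        return int(self.values.sum())

    def masked(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Return a copy with the given (row, col) entries set to 0."""
        out = self.values.copy()
        for i, j in pairs:
            out[i, j] = 0
        return AssociationMatrix(self.mirna_names, self.disease_names, out)


@dataclass
class SimilarityMatrix:
    """Square named similarity matrix.

    ``kind`` records provenance: "functional", "semantic", "credibility",
    "integrated", "filtered" or "generic".  Symmetry is checked (within
    1e-8) at construction and recorded, never silently enforced — the
    row-wise filter legitimately produces asymmetric output.
    """

    names: list[str]
    values: np.ndarray
    kind: str = "generic"
    symmetric: bool = field(init=False)

    def __post_init__(self) -> None:
        _check_unique(self.names, "similarity axis")
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.names)
        if self.values.shape != (k, k):
            raise DataFormatError(
                f"similarity matrix shape {self.values.shape} does not match {k} labels"
            )
        if not np.isfinite(self.values).all():
            raise DataFormatError("similarity matrix entries must be finite")
        self.symmetric = bool(
            np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL, rtol=0.0)
        )

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class OntologyInput:
    """Flattened disease ontology: term DAG plus a disease-to-term mapping."""

    edges: list[tuple[str, str]]  # (child term, parent term)
    disease_terms: dict[str, str]

    def __post_init__(self) -> None:
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise DataFormatError("ontology edge relation contains a cycle")
        self._graph = g

    def graph(self) -> nx.DiGraph:
        """Child-to-parent term graph."""
        return self._graph


@dataclass
class ScoreMatrix:
    """n x m real matrix F of predicted association scores."""

    mirna_names: list[str]
    disease_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.mirna_names, "miRNA axis")
        _check_unique(self.disease_names, "disease axis")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_names), len(self.disease_names)):
            raise DataFormatError("score matrix shape does not match axis labels")
        if not np.isfinite(self.values).all():
            raise DataFormatError("score matrix entries must be finite")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_associations(path: str | Path, sep: str = "\t") -> AssociationMatrix:
    """Read a two-column (miRNA, disease) edge list into an adjacency matrix.

    Axis orders follow first appearance in the file; duplicate rows
    collapse to a single association.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not all(parts):
                raise DataFormatError(
                    f"{path}: line {lineno}: expected two non-empty fields, got {line!r}"
                )
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise DataFormatError(f"{path}: empty association file")
    mirnas = list(dict.fromkeys(p[0] for p in pairs))
    diseases = list(dict.fromkeys(p[1] for p in pairs))
    mi = {name: i for i, name in enumerate(mirnas)}
    di = {name: j for j, name in enumerate(diseases)}
    a = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for mirna, disease in pairs:
        a[mi[mirna], di[disease]] = 1
    return AssociationMatrix(mirnas, diseases, a)


def write_associations(assoc: AssociationMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the known associations of A as a two-column edge list."""
    rows, cols = np.nonzero(assoc.values)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{assoc.mirna_names[i]}{sep}{assoc.disease_names[j]}\n")


def read_similarity(path: str | Path, sep: str = "\t", kind: str = "generic") -> SimilarityMatrix:
    """Read a square labelled similarity matrix (header row + label column)."""
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise DataFormatError(f"{path}: cannot parse similarity matrix: {exc}") from exc
    if frame.shape[0] != frame.shape[1]:
        raise DataFormatError(
            f"{path}: similarity matrix must be square, got {frame.shape}"
        )
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise DataFormatError(f"{path}: header labels do not match row labels")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataFormatError(f"{path}: non-numeric cell in similarity matrix")
    return SimilarityMatrix(list(frame.index.astype(str)), values, kind=kind)


def write_similarity(sim: SimilarityMatrix, path: str | Path, sep: str = "\t") -> None:
    frame = pd.DataFrame(sim.values, index=sim.names, columns=sim.names)
    frame.to_csv(path, sep=sep, float_format="%.12g")


def read_ontology(
    edges_path: str | Path, terms_path: str | Path, sep: str = "\t"
) -> OntologyInput:
    """Read a (child, parent) term edge list and a (disease, term) mapping."""
    edges: list[tuple[str, str]] = []
    with open(edges_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not all(parts):
                raise DataFormatError(
                    f"{edges_path}: line {lineno}: expected (child, parent)"
                )
            edges.append((parts[0], parts[1]))
    terms: dict[str, str] = {}
    with open(terms_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not all(parts):
                raise DataFormatError(
                    f"{terms_path}: line {lineno}: expected (disease, term)"
                )
            terms[parts[0]] = parts[1]
    return OntologyInput(edges, terms)


def align_similarity(sim: SimilarityMatrix, names: Sequence[str]) -> SimilarityMatrix:
    """Reorder a similarity matrix to the canonical axis order ``names``.

    Labels in the file that the association matrix does not know are
    dropped with a warning; a label missing from the file is an error,
    because the voting method needs a similarity row per entity.
    """
    index = {name: i for i, name in enumerate(sim.names)}
    missing = [name for name in names if name not in index]
    if missing:
        raise DataFormatError(
            f"similarity matrix lacks required labels: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    extra = [name for name in sim.names if name not in set(names)]
    if extra:
        logger.warning(
            "dropping %d similarity labels absent from the association matrix "
            "(e.g. %s)", len(extra), extra[:3],
        )
    order = [index[name] for name in names]
    return SimilarityMatrix(list(names), sim.values[np.ix_(order, order)], kind=sim.kind)


def write_rankings(
    scores: ScoreMatrix, assoc: AssociationMatrix, path: str | Path, sep: str = "\t"
) -> pd.DataFrame:
    """Write all pairs ranked by descending score.

    Columns: miRNA, disease, score, known flag.  Ties are broken by
    (miRNA index, disease index) ascending so output is deterministic.
    Returns the table that was written.
    """
    if (
        scores.mirna_names != assoc.mirna_names
        or scores.disease_names != assoc.disease_names
    ):
        raise DataFormatError("score and association matrices do not share axes")
    if scores.values.size == 0:
        raise DataFormatError("empty score matrix")
    n, m = scores.values.shape
    ii, jj = np.unravel_index(np.arange(n * m), (n, m))
    flat = scores.values.ravel()
    order = np.lexsort((jj, ii, -flat))
    table = pd.DataFrame(
        {
            "miRNA": [assoc.mirna_names[i] for i in ii[order]],
            "disease": [assoc.disease_names[j] for j in jj[order]],
            "score": flat[order],
            "known": assoc.values.ravel()[order].astype(int),
        }
    )
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return table
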