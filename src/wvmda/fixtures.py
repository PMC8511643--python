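"""Synthetic miRNA-disease networks with planted group structure.

The generator emulates the statistical shape of curated association
data: a sparse binary bipartite matrix (default density 3%, the scale of
real curated collections) whose associations concentrate on matching
latent groups — the standing assumption that functionally similar
miRNAs associate with similar diseases.  Alongside A it produces

* a miRNA functional-similarity matrix: high within a group, low
  across, jittered, symmetrised, unit diagonal;
* per-disease ancestor DAGs drawn from a random tree whose branches
  follow the groups, so same-group diseases share ancestors and inherit
  high semantic similarity.

With ``within_group_boost = 1`` the associations become independent of
the groups: the null network used for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, OntologyInput, SimilarityMatrix
from .semantic_similarity import DiseaseDAG, dag_from_ontology

CROSS_GROUP_SIMILARITY = 0.1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic network generator.

    ``density`` is the expected fraction of verified pairs;
    ``within_group_boost`` the ratio of in-group to out-group
    association probability (1 = no planted signal); ``sim_noise`` the
    half-width of the uniform jitter on similarity entries.
    """

    n_mirna: int = 60
    n_disease: int = 40
    n_groups: int = 4
    density: float = 0.03
    within_group_boost: float = 10.0
    sim_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if self.n_groups > min(self.n_mirna, self.n_disease):
            raise ValueError("more groups than entities on an axis")
        if self.within_group_boost < 1:
            raise ValueError("within_group_boost must be >= 1")


def _group_labels(n: int, n_groups: int) -> np.ndarray:
    return np.arange(n) % n_groups


def make_network(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[AssociationMatrix, SimilarityMatrix, list[DiseaseDAG]]:
    """Generate (A, FM, disease DAGs) for one seeded synthetic network.

    In-group pairs associate with probability ``boost * p0`` and
    out-group pairs with ``p0``, where ``p0`` is chosen so the expected
    overall density equals ``spec.density``.
    """
    rng = np.random.default_rng(spec.seed)
    mirna_names = [f"mirna{i:03d}" for i in range(spec.n_mirna)]
    disease_names = [f"disease{j:03d}" for j in range(spec.n_disease)]
    gm = _group_labels(spec.n_mirna, spec.n_groups)
    gd = _group_labels(spec.n_disease, spec.n_groups)
    match = gm[:, None] == gd[None, :]
    f_in = match.mean()
    p_out = spec.density / (f_in * spec.within_group_boost + 1.0 - f_in)
    p_in = spec.within_group_boost * p_out
    if p_in > 1.0:
        raise ValueError(
            f"infeasible density: in-group association probability {p_in:.3f} > 1"
        )
    prob = np.where(match, p_in, p_out)
    a = (rng.random(prob.shape) < prob).astype(np.int8)
    assoc = AssociationMatrix(mirna_names, disease_names, a)

    same = (gm[:, None] == gm[None, :]).astype(float)
    fm = same + CROSS_GROUP_SIMILARITY * (1.0 - same)
    fm = fm + rng.uniform(-spec.sim_noise, spec.sim_noise, fm.shape)
    fm = np.clip(0.5 * (fm + fm.T), 0.0, 1.0)
    np.fill_diagonal(fm, 1.0)
    functional = SimilarityMatrix(mirna_names, fm, kind="functional")

    ontology = make_ontology(spec, disease_names, gd, rng)
    dags = [dag_from_ontology(ontology, d) for d in disease_names]
    return assoc, functional, dags


def make_ontology(
    spec: FixtureSpec,
    disease_names: list[str],
    disease_groups: np.ndarray,
    rng: np.random.Generator,
) -> OntologyInput:
    """Random group-structured term tree: every disease term hangs under
    its group's ancestor chain, all chains meet at a common root.

    Each disease sits at a randomly drawn depth below its group anchor
    (0-2 private intermediate terms), mirroring how real ontology terms
    for related diseases share ancestors without being interchangeable.
    """
    edges: list[tuple[str, str]] = []
    group_anchor: dict[int, str] = {}
    for g in range(spec.n_groups):
        depth = int(rng.integers(1, 3))  # 1 or 2 shared group levels
        parent = "T:root"
        for level in range(depth):
            node = f"T:g{g}l{level}"
            edges.append((node, parent))
            parent = node
        group_anchor[g] = parent
    terms: dict[str, str] = {}
    for name, g in zip(disease_names, disease_groups):
        parent = group_anchor[int(g)]
        for level in range(int(rng.integers(0, 3))):  # 0-2 private levels
            node = f"T:{name}l{level}"
            edges.append((node, parent))
            parent = node
        term = f"T:{name}"
        edges.append((term, parent))
        terms[name] = term
    return OntologyInput(edges, terms)


def permuted_null(assoc: AssociationMatrix, seed: int = 0) -> AssociationMatrix:
    """Permutation null: shuffle both axes of A relative to their labels.

    Degree sequences are preserved exactly, but any alignment between
    associations and the similarity networks is destroyed.
    """
    rng = np.random.default_rng(seed)
    rows = rng.permutation(assoc.n)
    cols = rng.permutation(assoc.m)
    return AssociationMatrix(
        list(assoc.mirna_names), list(assoc.disease_names),
        assoc.values[np.ix_(rows, cols)],
    )


def make_worked_example() -> dict:
    """The two tiny hand-checkable instances used in docs and golden tests.

    ``credibility``: 3 miRNAs x 2 diseases; with delta = 2 and base code
    -1 its rescaled credibility similarity has off-diagonals
    (m1,m2) = 0, (m1,m3) = 1, (m2,m3) = 1.

    ``scoring``: the smallest informative voting instance (A = I with
    explicit similarities), evaluated at e = 0.
    """
    return {
        "credibility": {
            "association": AssociationMatrix(
                ["m1", "m2", "m3"], ["d1", "d2"],
                np.array([[1, 0], [0, 1], [1, 1]]),
            ),
            "delta": 2.0,
            "base_code": -1.0,
        },
        "scoring": {
            "association": AssociationMatrix(
                ["m1", "m2"], ["d1", "d2"], np.eye(2, dtype=int)
            ),
            "mirna_sim": SimilarityMatrix(
                ["m1", "m2"], np.array([[1.0, 0.5], [0.5, 1.0]]), kind="integrated"
            ),
            "disease_sim": SimilarityMatrix(
                ["d1", "d2"], np.array([[1.0, 0.2], [0.2, 1.0]]), kind="integrated"
            ),
            "e": 0.0,
        },
    }


def ontology_from_dags(dags: list[DiseaseDAG]) -> OntologyInput:
    """Flatten a list of disease DAGs back into a single ontology input."""
    edges = sorted(set().union(*(d.edges for d in dags)))
    return OntologyInput(list(edges), {d.disease: d.term for d in dags})
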