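"""Cross-validated evaluation: 5-fold CV, global LOOCV, ROC/AUC.

Both protocols mask verified associations, rebuild everything downstream
of A (credibility similarity, integration, filtering, voter counts and
scores) from the surviving training associations only, and rank the
masked positives against all pairs that are 0 in the *full* matrix.  The
external functional and semantic similarities derive from independent
data and are therefore fixed across folds; only structures computed from
A are refit, so no held-out information can leak into a fold's model.

AUC is the rank-based (Mann-Whitney) statistic
P(score_pos > score_neg) + 0.5 P(tie), identical to the trapezoidal area
under the threshold-swept ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .data_io import AssociationMatrix, OntologyInput, SimilarityMatrix
from .pipeline import PipelineParams, predict_scores
from .semantic_similarity import DiseaseDAG, semantic_similarity_matrix

N_FOLDS = 5
DEFAULT_REPEATS = 5


@dataclass
class CVResult:
    """Per-fold AUCs (all repeats), their mean, and pooled ROC points."""

    fold_aucs: list[float]
    mean_auc: float
    roc_points: list[tuple[float, float]]


def auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Rank-based AUC with midrank tie handling."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _resolve_semantic(
    sd_or_ontology: SimilarityMatrix | OntologyInput | Sequence[DiseaseDAG],
    diseases: list[str],
    omega: float,
) -> SimilarityMatrix:
    if isinstance(sd_or_ontology, SimilarityMatrix):
        return sd_or_ontology
    if isinstance(sd_or_ontology, OntologyInput):
        from .semantic_similarity import semantic_similarity_from_ontology

        return semantic_similarity_from_ontology(sd_or_ontology, diseases, omega)
    sd = semantic_similarity_matrix(list(sd_or_ontology), omega)
    if sd.names != diseases:
        raise ValueError("disease DAG order does not match the association matrix")
    return sd


def five_fold_cv(
    assoc: AssociationMatrix,
    functional_sim: SimilarityMatrix,
    sd_or_ontology: SimilarityMatrix | OntologyInput | Sequence[DiseaseDAG],
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
    repeats: int = DEFAULT_REPEATS,
) -> CVResult:
    """Five-fold cross-validation over the verified associations.

    The positives are randomly split (seeded) into five folds; for each
    fold the model is rebuilt on the other four fifths and the held-out
    positives are ranked against every pair that is 0 in the full
    matrix.  The split is redrawn ``repeats`` times and all fold AUCs
    are pooled into the mean.
    """
    sd = _resolve_semantic(sd_or_ontology, assoc.disease_names, params.omega)
    positives = np.argwhere(assoc.values == 1)
    if len(positives) < N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS} known associations")
    neg_mask = assoc.values == 0
    fold_aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        order = rng.permutation(len(positives))
        for fold in np.array_split(order, N_FOLDS):
            held = positives[fold]
            train = assoc.masked(map(tuple, held))
            f = predict_scores(train, functional_sim, sd, params).values
            pos_scores = f[held[:, 0], held[:, 1]]
            neg_scores = f[neg_mask]
            fold_aucs.append(auc(pos_scores, neg_scores))
            if rep == 0:
                pooled_scores.append(np.concatenate([pos_scores, neg_scores]))
                pooled_labels.append(
                    np.concatenate(
                        [np.ones(len(pos_scores)), np.zeros(len(neg_scores))]
                    )
                )
    fpr, tpr, _ = roc_curve(
        np.concatenate(pooled_labels), np.concatenate(pooled_scores)
    )
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


def global_loocv(
    assoc: AssociationMatrix,
    functional_sim: SimilarityMatrix,
    sd_or_ontology: SimilarityMatrix | OntologyInput | Sequence[DiseaseDAG],
    params: PipelineParams = PipelineParams(),
) -> float:
    """Global leave-one-out cross-validation AUC.

    Each verified association is masked in turn, the model is rebuilt,
    and the left-out pair's score is ranked against all unknown pairs of
    the whole matrix; the per-trial AUCs are averaged.  Deterministic.
    """
    sd = _resolve_semantic(sd_or_ontology, assoc.disease_names, params.omega)
    positives = np.argwhere(assoc.values == 1)
    if len(positives) < 2:
        raise ValueError("need at least two known associations")
    neg_mask = assoc.values == 0
    trial_aucs = []
    for i, j in positives:
        train = assoc.masked([(i, j)])
        f = predict_scores(train, functional_sim, sd, params).values
        trial_aucs.append(auc([f[i, j]], f[neg_mask]))
    return float(np.mean(trial_aucs))


def hyperparameter_sweep(
    assoc: AssociationMatrix,
    functional_sim: SimilarityMatrix,
    sd_or_ontology: SimilarityMatrix | OntologyInput | Sequence[DiseaseDAG],
    deltas: Sequence[float],
    ratios: Sequence[float],
    e: float | None = None,
    seed: int = 0,
    repeats: int = 1,
):
    """Mean 5CV AUC over a (delta, r) grid at fixed group exponent e.

    Returns a pandas DataFrame with columns delta, r, mean_auc.
    """
    import pandas as pd

    base = PipelineParams() if e is None else PipelineParams(e=e)
    records = []
    for delta in deltas:
        for r in ratios:
            params = PipelineParams(
                delta=delta, base_code=base.base_code, omega=base.omega,
                r=r, e=base.e, symmetrize=base.symmetrize,
            )
            result = five_fold_cv(
                assoc, functional_sim, sd_or_ontology, params,
                seed=seed, repeats=repeats,
            )
            records.append({"delta": delta, "r": r, "mean_auc": result.mean_auc})
    return pd.DataFrame.from_records(records)
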