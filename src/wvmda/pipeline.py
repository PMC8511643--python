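"""End-to-end prediction pipeline: credibility -> integrate -> filter -> vote."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .credibility_similarity import (
    DEFAULT_BASE_CODE,
    DEFAULT_DELTA,
    credibility_similarity,
    integrate,
)
from .data_io import (
    AssociationMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    align_similarity,
    read_associations,
    read_ontology,
    read_similarity,
    write_rankings,
)
from .semantic_similarity import DEFAULT_OMEGA, semantic_similarity_from_ontology
from .similarity_filter import DEFAULT_RATIO, filter_matrix
from .voting import DEFAULT_EXPONENT, score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All model hyperparameters in one place.

    delta      credibility of a verified association (> 1)
    base_code  credibility code of an undetermined pair
    omega      semantic contribution decay per ontology level
    r          hypothetical-position ratio of the similarity filter
    e          group-weight exponent of the voting stage
    symmetrize re-symmetrise filtered similarities (off by default)
    """

    delta: float = DEFAULT_DELTA
    base_code: float = DEFAULT_BASE_CODE
    omega: float = DEFAULT_OMEGA
    r: float = DEFAULT_RATIO
    e: float = DEFAULT_EXPONENT
    symmetrize: bool = False


def predict_scores(
    assoc: AssociationMatrix,
    functional_sim: SimilarityMatrix,
    semantic_sim: SimilarityMatrix,
    params: PipelineParams = PipelineParams(),
) -> ScoreMatrix:
    """Score every miRNA-disease pair from A and the two external similarities.

    Builds credibility similarity on both axes of A, averages it with the
    functional (miRNA) and semantic (disease) similarity, filters both
    integrated matrices row-wise, and runs the weighted vote.
    """
    cm = credibility_similarity(assoc, "mirna", params.delta, params.base_code)
    cd = credibility_similarity(assoc, "disease", params.delta, params.base_code)
    m = integrate(functional_sim, cm)
    d = integrate(semantic_sim, cd)
    mf = filter_matrix(m, params.r, symmetrize=params.symmetrize)
    df = filter_matrix(d, params.r, symmetrize=params.symmetrize)
    return score(assoc, mf, df, params.e)


@dataclass
class RunConfig:
    """File-level configuration of a full prediction run."""

    associations: Path
    mirna_similarity: Path
    out: Path
    disease_similarity: Path | None = None
    ontology_edges: Path | None = None
    disease_terms: Path | None = None
    sep: str = "\t"
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if self.disease_similarity is None and (
            self.ontology_edges is None or self.disease_terms is None
        ):
            raise ValueError(
                "provide either a disease similarity matrix or an ontology "
                "(edge list plus disease-term mapping)"
            )


def run_pipeline(config: RunConfig) -> ScoreMatrix:
    """Execute the full pipeline from files and write the ranked predictions."""

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("read associations")
    assoc = read_associations(config.associations, sep=config.sep)
    logger.info(
        "association matrix: %d miRNAs x %d diseases, %d known associations",
        assoc.n, assoc.m, assoc.n_known,
    )

    stage("read miRNA functional similarity")
    fm = align_similarity(
        read_similarity(config.mirna_similarity, sep=config.sep, kind="functional"),
        assoc.mirna_names,
    )

    if config.disease_similarity is not None:
        stage("read disease semantic similarity")
        sd = align_similarity(
            read_similarity(config.disease_similarity, sep=config.sep, kind="semantic"),
            assoc.disease_names,
        )
    else:
        stage("compute disease semantic similarity from ontology")
        ontology = read_ontology(
            config.ontology_edges, config.disease_terms, sep=config.sep
        )
        sd = semantic_similarity_from_ontology(
            ontology, assoc.disease_names, config.params.omega
        )

    stage("credibility similarity, integration, filtering, voting")
    logger.info(
        "parameters: delta=%g base_code=%g omega=%g r=%g e=%g",
        config.params.delta, config.params.base_code, config.params.omega,
        config.params.r, config.params.e,
    )
    result = predict_scores(assoc, fm, sd, config.params)

    stage("write rankings")
    write_rankings(result, assoc, config.out, sep=config.sep)
    logger.info("wrote %d ranked pairs to %s", result.values.size, config.out)
    return result
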