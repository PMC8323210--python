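"""End-to-end orchestration: preprocess a cohort, compute pair similarities,
learn the metric from an expert-labeled patient subset, snowball-propagate
scores to every pair, and expose the matrices the kNN harness consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (assemble_numeric, exclude_outcome_codes,
                     select_popular_comorbidities)
from .knn import scores_to_matrix
from .metric import TraceQuotientMetricLearner
from .propagation import SnowballPropagator, default_batch_size
from .similarity import build_fragment_corpus, pairwise_similarity_table
from .synthetic import OracleConfig, expert_score_oracle
from .text import TextSchema

__all__ = ["SimilarityPipelineResult", "run_similarity_pipeline", "prepare_cohort"]


@dataclass
class SimilarityPipelineResult:
    """Everything the downstream prediction harness needs."""

    ids: list
    corpus: object
    schema: TextSchema
    pair_table: pd.DataFrame          # id_a, id_b, v1..v12 (+ score after propagation)
    labeled_ids: list                 # the expert-scored patient subset
    labeled_mask: np.ndarray          # rows of pair_table that were expert-labeled
    expert_scores: np.ndarray         # scores of the labeled rows
    learner: TraceQuotientMetricLearner
    propagator: SnowballPropagator
    similarity_matrix: np.ndarray     # (n, n) propagated patient similarity
    numeric: pd.DataFrame             # Euclidean representation (patients x features)
    numeric_groups: dict


def prepare_cohort(patients, r_text: int = 44, independent=None,
                   popularity_threshold: float = 0.05, max_popular: int | None = None):
    """Shared preprocessing: strip outcome codes, build the fragment corpus,
    derive the text schema from the report corpus, and pick the popular
    comorbidities for the numeric representation.

    Returns ``(cohort, corpus, schema, popular)`` with the cohort sorted by id
    (the canonical order used everywhere downstream).
    """
    cohort = sorted(exclude_outcome_codes(patients), key=lambda p: p.id)
    corpus = build_fragment_corpus(cohort)
    docs = [sorted(p.report_tokens) for p in cohort]
    schema = TextSchema.from_documents(docs, r=r_text, independent=independent)
    popular = select_popular_comorbidities(cohort, popularity_threshold)
    if max_popular is not None:
        popular = popular[:max_popular]
    return cohort, corpus, schema, popular


def run_similarity_pipeline(patients, n_labeled_patients: int = 30,
                            oracle: OracleConfig | None = None,
                            rank: int = 2, batch_size="auto", seed: int = 0,
                            r_text: int = 44, independent=None,
                            metric="learned",
                            max_popular: int | None = None) -> SimilarityPipelineResult:
    """Run the full similarity-learning pipeline on a preprocessed-able cohort.

    A random subset of ``n_labeled_patients`` patients is "shown to the
    expert": every pair among them receives an oracle score, the Mahalanobis
    metric is learned from those labeled pairs, and scores are snowballed to
    all remaining pairs under the learned metric (``metric="identity"``
    propagates under the plain Euclidean metric instead, as a baseline).
    """
    cohort, corpus, schema, popular = prepare_cohort(
        patients, r_text=r_text, independent=independent, max_popular=max_popular)
    ids = [p.id for p in cohort]
    table = pairwise_similarity_table(cohort, corpus, schema)
    V = table[[f"v{i}" for i in range(1, 13)]].to_numpy()

    rng = np.random.default_rng(seed)
    if not (3 <= n_labeled_patients <= len(ids)):
        raise ValueError("n_labeled_patients must lie in [3, n_patients]")
    labeled_ids = sorted(rng.choice(ids, size=n_labeled_patients, replace=False).tolist())
    labeled_set = set(labeled_ids)
    labeled_mask = np.array([
        (a in labeled_set) and (b in labeled_set)
        for a, b in zip(table["id_a"], table["id_b"])
    ])

    oracle = oracle if oracle is not None else OracleConfig(seed=seed + 1)
    expert_scores = np.atleast_1d(expert_score_oracle(V[labeled_mask], oracle))

    learner = TraceQuotientMetricLearner(rank=rank)
    learner.fit(V[labeled_mask], expert_scores)

    C = None if metric == "identity" else learner.metric_matrix_
    y = np.full(V.shape[0], np.nan)
    y[labeled_mask] = expert_scores
    propagator = SnowballPropagator(metric=C, batch_size=batch_size).fit(V, y)
    table = table.copy()
    table["score"] = propagator.scores_

    S = scores_to_matrix(table, ids)
    numeric, groups = assemble_numeric(cohort, popular, schema)

    return SimilarityPipelineResult(
        ids=ids, corpus=corpus, schema=schema, pair_table=table,
        labeled_ids=labeled_ids, labeled_mask=labeled_mask,
        expert_scores=expert_scores, learner=learner, propagator=propagator,
        similarity_matrix=S, numeric=numeric, numeric_groups=groups,
    )
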