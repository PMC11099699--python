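"""Scikit-learn-style estimators over the mapping, EM and prediction stages.

These wrap the module-level operations behind the familiar
``fit`` / ``transform`` / ``predict`` surface with ``get_params`` /
``set_params`` and trailing-underscore fitted attributes, so the stages
compose with sklearn model-selection utilities.  X is an
:class:`~domap.annotation_io.AnnotationCorpus` (or a mapping table /
protein->domain map, per estimator), not an array.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .annotation_io import AnnotationCorpus
from .em_core import EmConfig, build_triplets, compute_e_scores, run_em
from .mapping_core import (
    DEFAULT_ALPHA,
    DEFAULT_N_GRID,
    DEFAULT_S_GRID,
    MappingTable,
    build_initial_mappings,
    filter_mappings,
)
from .ontology_io import OntologyDag
from .pipeline import mine_mappings
from .prediction import (
    DEFAULT_SCORE_FLOOR,
    PredictionSet,
    naive_baseline,
    predict_functions,
)


def _check_corpus(X) -> AnnotationCorpus:
    if not isinstance(X, AnnotationCorpus):
        raise TypeError(f"expected an AnnotationCorpus, got {type(X).__name__}")
    if not X.shared_proteins():
        raise ValueError("corpus has no protein present in both annotation maps")
    return X


class CooccurrenceMapper(BaseEstimator):
    """Learn reliable domain->GO mappings from a co-annotation corpus.

    Fitting builds the initial mapping table, a column-shuffled null, selects
    (S, n) thresholds by the KS grid scan (unless ``auto_threshold=False``,
    in which case ``s_min`` / ``n_min`` are used as given), and stores the
    filtered table.

    Attributes
    ----------
    mapping_table_ : MappingTable         initial (unfiltered) mappings
    randomized_table_ : MappingTable      the shuffled null
    threshold_selection_ : ThresholdSelection or None
    s_min_, n_min_ : the thresholds actually applied
    filtered_table_ : MappingTable        the reliable mapping set
    """

    def __init__(
        self,
        s_min: float = 0.2,
        n_min: int = 2,
        auto_threshold: bool = True,
        s_grid=DEFAULT_S_GRID,
        n_grid=DEFAULT_N_GRID,
        alpha: float = DEFAULT_ALPHA,
        safety_margin: bool = True,
        shuffle_unit: str = "triplet",
        random_state: int = 0,
    ):
        self.s_min = s_min
        self.n_min = n_min
        self.auto_threshold = auto_threshold
        self.s_grid = s_grid
        self.n_grid = n_grid
        self.alpha = alpha
        self.safety_margin = safety_margin
        self.shuffle_unit = shuffle_unit
        self.random_state = random_state

    def fit(self, X, y=None):
        corpus = _check_corpus(X)
        if self.auto_threshold:
            result = mine_mappings(
                corpus,
                seed=self.random_state,
                s_grid=self.s_grid,
                n_grid=self.n_grid,
                alpha=self.alpha,
                safety_margin=self.safety_margin,
                shuffle_unit=self.shuffle_unit,
            )
            self.mapping_table_ = result.mapping_table
            self.randomized_table_ = result.randomized_table
            self.threshold_selection_ = result.selection
            self.s_min_, self.n_min_ = result.s_min, result.n_min
            self.filtered_table_ = result.filtered_table
            self.safety_applied_ = result.safety_applied
        else:
            self.mapping_table_ = build_initial_mappings(corpus)
            self.randomized_table_ = None
            self.threshold_selection_ = None
            self.s_min_, self.n_min_ = self.s_min, self.n_min
            self.filtered_table_ = filter_mappings(
                self.mapping_table_, s_min=self.s_min, n_min=self.n_min
            )
            self.safety_applied_ = False
        return self

    def transform(self, X=None) -> MappingTable:
        if not hasattr(self, "filtered_table_"):
            raise NotFittedError("CooccurrenceMapper is not fitted")
        return self.filtered_table_

    def fit_transform(self, X, y=None) -> MappingTable:
        return self.fit(X).transform()


class EMAssociation(BaseEstimator):
    """Estimate per-pair association probabilities theta and E scores by EM.

    Triplets are restricted to pairs with co-occurrence S >= ``restrict_s_min``
    (set to 0 to use every pair) before the EM runs, since leave-one-out E
    scoring reruns the EM once per pair.

    Attributes
    ----------
    triplets_ : TripletSet
    theta_matrix_ : ThetaMatrix (with log_likelihood_trace)
    theta_ : dict (domain, go) -> probability
    evidence_ : EvidenceTable or None
    results_ : DataFrame with n, s, theta_init, theta[, e] per pair
    """

    def __init__(
        self,
        em_alpha: float = 0.0,
        em_beta: float = 0.0,
        max_iterations: int = 150,
        rel_tolerance: float = 1e-4,
        epsilon: float = 1e-12,
        e_score_iterations: int = 10,
        restrict_s_min: float = 0.1,
        compute_e: bool = True,
    ):
        self.em_alpha = em_alpha
        self.em_beta = em_beta
        self.max_iterations = max_iterations
        self.rel_tolerance = rel_tolerance
        self.epsilon = epsilon
        self.e_score_iterations = e_score_iterations
        self.restrict_s_min = restrict_s_min
        self.compute_e = compute_e

    def _config(self) -> EmConfig:
        return EmConfig(
            alpha=self.em_alpha,
            beta=self.em_beta,
            max_iterations=self.max_iterations,
            rel_tolerance=self.rel_tolerance,
            epsilon=self.epsilon,
            e_score_iterations=self.e_score_iterations,
        )

    def fit(self, X, y=None):
        corpus = _check_corpus(X)
        config = self._config()
        table = build_initial_mappings(corpus)
        restrict = None
        if self.restrict_s_min > 0:
            keep = table.rows["s"] >= self.restrict_s_min
            restrict = MappingTable(
                rows=table.rows.loc[keep].reset_index(drop=True),
                provenance=table.provenance,
                corpus_digest=table.corpus_digest,
            )
        triplets = build_triplets(corpus, restrict_to=restrict)
        matrix = run_em(triplets, corpus, config)
        self.triplets_ = triplets
        self.theta_matrix_ = matrix
        self.theta_ = matrix.theta
        self.evidence_ = (
            compute_e_scores(matrix, triplets, corpus, config)
            if self.compute_e
            else None
        )

        support = matrix.n_arr
        theta_init = support / (support + matrix.z_arr)
        rows = {
            "domain_id": [d for d, _ in matrix.pairs],
            "go_id": [g for _, g in matrix.pairs],
            "n": support.astype(int),
            "s": [
                2.0 * n / (2.0 * n + z) for n, z in zip(support, matrix.z_arr)
            ],
            "theta_init": theta_init,
            "theta": matrix.theta_arr,
        }
        if self.evidence_ is not None:
            rows["e"] = [self.evidence_.e[p] for p in matrix.pairs]
            rows["capped"] = [p in self.evidence_.capped for p in matrix.pairs]
        self.results_ = pd.DataFrame(rows)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise NotFittedError("EMAssociation is not fitted")
        return self.results_


class DomainFunctionPredictor(BaseEstimator):
    """Predict protein GO terms by propagating a learned mapping table.

    ``fit`` stores the mapping table (a MappingTable or DataFrame with a
    score column per ``score_mode``); ``predict`` takes a
    protein -> domain-set map and returns a :class:`PredictionSet`.
    """

    def __init__(
        self,
        score_mode: str = "S",
        score_floor: float = DEFAULT_SCORE_FLOOR,
        dag: Optional[OntologyDag] = None,
    ):
        self.score_mode = score_mode
        self.score_floor = score_floor
        self.dag = dag

    def fit(self, X, y=None):
        df = X.rows if hasattr(X, "rows") else X
        if len(df) == 0:
            raise ValueError("empty mapping table")
        self.mappings_ = df
        return self

    def predict(self, X: Mapping[str, Set[str]]) -> PredictionSet:
        if not hasattr(self, "mappings_"):
            raise NotFittedError("DomainFunctionPredictor is not fitted")
        return predict_functions(
            self.mappings_,
            X,
            dag=self.dag,
            score_mode=self.score_mode,
            score_floor=self.score_floor,
        )


class NaiveFrequencyPredictor(BaseEstimator):
    """CAFA Naive baseline: term frequency in the training corpus as score."""

    def fit(self, X, y=None):
        if isinstance(X, AnnotationCorpus):
            X = X.protein_go
        if not X:
            raise ValueError("empty training annotation set")
        self.train_go_ = {p: set(t) for p, t in X.items()}
        return self

    def predict(self, X: Iterable[str]) -> PredictionSet:
        if not hasattr(self, "train_go_"):
            raise NotFittedError("NaiveFrequencyPredictor is not fitted")
        return naive_baseline(self.train_go_, X)
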