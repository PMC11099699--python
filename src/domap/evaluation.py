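"""Protein-centric CAFA-style evaluation: Fmax, Smin and coverage.

At each score threshold tau, a protein's predicted term set is everything it
was assigned with score >= tau.  Precision at tau averages TP/(TP+FP) over
the m(tau) proteins with at least one prediction at that threshold; recall
averages TP/(TP+FN) over n_eval proteins — all benchmark proteins in *full*
mode, or only proteins the method predicts at all in *partial* mode.  Fmax is
the maximum harmonic mean over the threshold grid.  Smin replaces counts with
information content: remaining uncertainty ru(tau) sums the IC of missed true
terms and misinformation mi(tau) the IC of wrong predicted terms, both
averaged over all benchmark proteins, and Smin = min_tau sqrt(ru^2 + mi^2).

Namespace roots are excluded from both predictions and truth before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import math

import numpy as np
import pandas as pd

from .ontology_io import InformationContentTable, OntologyDag
from .prediction import PredictionSet

DEFAULT_TAU_GRID = tuple(round(0.01 * i, 2) for i in range(1, 101))


@dataclass
class BenchmarkSet:
    """Ground-truth protein -> GO sets (ancestor-closed, roots excluded)."""

    truth: Dict[str, Set[str]]
    namespace: str = ""
    knowledge_type: str = "no-knowledge"

    def __post_init__(self) -> None:
        self.truth = {p: set(t) for p, t in self.truth.items() if t}

    def __len__(self) -> int:
        return len(self.truth)

    @classmethod
    def from_tsv(cls, path, namespace: str = "", knowledge_type: str = "no-knowledge"):
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns[:2])
        truth: Dict[str, Set[str]] = {}
        for p, t in zip(df[cols[0]], df[cols[1]]):
            truth.setdefault(p, set()).add(t)
        return cls(truth=truth, namespace=namespace, knowledge_type=knowledge_type)


@dataclass
class EvaluationResult:
    fmax: float
    tau_at_fmax: float
    smin: Optional[float]
    tau_at_smin: Optional[float]
    coverage: float
    mode: str
    namespace: str = ""
    pr_curve: List[Tuple[float, float, float]] = field(default_factory=list)
    ru_mi_curve: List[Tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "fmax": self.fmax,
            "tau": self.tau_at_fmax,
            "smin": self.smin,
            "tau_smin": self.tau_at_smin,
            "coverage": self.coverage,
            "coverage_percent": 100.0 * self.coverage,
            "mode": self.mode,
            "namespace": self.namespace,
        }


def _clean(
    preds: PredictionSet, bench: BenchmarkSet, exclude_terms: Optional[Set[str]]
) -> Tuple[Dict[str, Dict[str, float]], Dict[str, Set[str]]]:
    exclude = exclude_terms or set()
    truth = {
        p: {t for t in ts if t not in exclude}
        for p, ts in bench.truth.items()
    }
    truth = {p: ts for p, ts in truth.items() if ts}
    scores = {
        p: {t: s for t, s in terms.items() if t not in exclude}
        for p, terms in preds.scores.items()
    }
    return scores, truth


def precision_recall_at_tau(
    preds: PredictionSet,
    bench: BenchmarkSet,
    tau: float,
    mode: str = "full",
    exclude_terms: Optional[Set[str]] = None,
) -> Tuple[Optional[float], float, int, int]:
    """Protein-centric precision and recall at one threshold.

    Returns (precision, recall, m_tau, n_eval); precision is None when no
    protein predicts anything at this threshold (the threshold is skipped
    when maximizing F).
    """
    if not bench.truth:
        raise ValueError("empty benchmark")
    scores, truth = _clean(preds, bench, exclude_terms)
    bench_proteins = sorted(truth)

    covered = {p for p in bench_proteins if scores.get(p)}
    n_eval = len(bench_proteins) if mode == "full" else len(covered)
    if mode not in ("full", "partial"):
        raise ValueError(f"unknown evaluation mode {mode!r}")

    precisions: List[float] = []
    recall_sum = 0.0
    m_tau = 0
    for p in bench_proteins:
        pred_terms = {t for t, s in scores.get(p, {}).items() if s >= tau}
        true_terms = truth[p]
        if pred_terms:
            m_tau += 1
            tp = len(pred_terms & true_terms)
            precisions.append(tp / len(pred_terms))
            recall_sum += tp / len(true_terms)
    precision = sum(precisions) / m_tau if m_tau else None
    recall = recall_sum / n_eval if n_eval else 0.0
    return precision, recall, m_tau, n_eval


def fmax(
    preds: PredictionSet,
    bench: BenchmarkSet,
    mode: str = "full",
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    exclude_terms: Optional[Set[str]] = None,
) -> Tuple[float, float, List[Tuple[float, float, float]]]:
    """Maximum F1 over the threshold grid; ties resolve to the smallest tau."""
    best_f, best_tau = 0.0, float(tau_grid[0])
    curve: List[Tuple[float, float, float]] = []
    for tau in tau_grid:
        pr, rc, m_tau, _ = precision_recall_at_tau(
            preds, bench, tau, mode=mode, exclude_terms=exclude_terms
        )
        if pr is None:
            continue
        f = 2 * pr * rc / (pr + rc) if (pr + rc) > 0 else 0.0
        curve.append((float(tau), pr, rc))
        if f > best_f:
            best_f, best_tau = f, float(tau)
    return best_f, best_tau, curve


def smin(
    preds: PredictionSet,
    bench: BenchmarkSet,
    ic: InformationContentTable,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    exclude_terms: Optional[Set[str]] = None,
) -> Tuple[float, float, List[Tuple[float, float, float]]]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold grid.

    ru(tau) and mi(tau) average over all benchmark proteins.  A benchmark or
    predicted term missing from the IC table is an error naming the term.
    """
    if not bench.truth:
        raise ValueError("empty benchmark")
    scores, truth = _clean(preds, bench, exclude_terms)
    for p, ts in truth.items():
        for t in ts:
            if t not in ic:
                raise ValueError(f"no information content for benchmark term {t}")
    for p, terms in scores.items():
        for t in terms:
            if t not in ic:
                raise ValueError(f"no information content for predicted term {t}")

    n = len(truth)
    best = (math.inf, float(tau_grid[0]))
    curve: List[Tuple[float, float, float]] = []
    for tau in tau_grid:
        ru_sum = mi_sum = 0.0
        for p, true_terms in truth.items():
            pred_terms = {t for t, s in scores.get(p, {}).items() if s >= tau}
            ru_sum += sum(ic[t] for t in true_terms - pred_terms)
            mi_sum += sum(ic[t] for t in pred_terms - true_terms)
        ru, mi = ru_sum / n, mi_sum / n
        dist = math.hypot(ru, mi)
        curve.append((float(tau), ru, mi))
        if dist < best[0]:
            best = (dist, float(tau))
    return best[0], best[1], curve


def coverage(preds: PredictionSet, bench: BenchmarkSet) -> float:
    """Fraction of benchmark proteins with at least one prediction."""
    if not bench.truth:
        raise ValueError("empty benchmark")
    return sum(1 for p in bench.truth if preds.scores.get(p)) / len(bench.truth)


def evaluate(
    preds: PredictionSet,
    bench: BenchmarkSet,
    ic: Optional[InformationContentTable] = None,
    mode: str = "full",
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    dag: Optional[OntologyDag] = None,
) -> EvaluationResult:
    """Full protein-centric evaluation; passing a dag excludes namespace roots."""
    exclude = set(dag.roots.values()) if dag is not None else None
    f, tau_f, pr_curve = fmax(preds, bench, mode=mode, tau_grid=tau_grid,
                              exclude_terms=exclude)
    s_val = tau_s = None
    ru_mi: List[Tuple[float, float, float]] = []
    if ic is not None:
        s_val, tau_s, ru_mi = smin(preds, bench, ic, tau_grid=tau_grid,
                                   exclude_terms=exclude)
    return EvaluationResult(
        fmax=f,
        tau_at_fmax=tau_f,
        smin=s_val,
        tau_at_smin=tau_s,
        coverage=coverage(preds, bench),
        mode=mode,
        namespace=bench.namespace,
        pr_curve=pr_curve,
        ru_mi_curve=ru_mi,
    )
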