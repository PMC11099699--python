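"""Protein function prediction by propagating domain-GO mappings.

A protein carrying domain D inherits every GO term mapped to D, scored by the
mapping's co-occurrence similarity S (already in (0, 1]) or by its min-max
scaled E score.  When several domains of one protein support the same term,
the maximum score wins.  A DAG-consistency pass then lifts each prediction's
score to all ancestor terms, as CAFA-style evaluation assumes parent scores
dominate child scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .ontology_io import OntologyDag

DEFAULT_SCORE_FLOOR = 0.01


@dataclass
class PredictionSet:
    """Scored (protein, GO term) predictions, unique per pair, scores in (0, 1]."""

    scores: Dict[str, Dict[str, float]]  # protein -> term -> score
    mode: str = "S"
    components: List[str] = field(default_factory=list)

    def proteins(self) -> Set[str]:
        return set(self.scores)

    def __len__(self) -> int:
        return sum(len(v) for v in self.scores.values())

    def records(self) -> List[Tuple[str, str, float]]:
        return [
            (p, t, s)
            for p in sorted(self.scores)
            for t, s in sorted(self.scores[p].items())
        ]

    def to_tsv(self, path) -> None:
        """CAFA submission style: protein_id<TAB>go_id<TAB>score."""
        with open(path, "w") as fh:
            for p, t, s in self.records():
                fh.write(f"{p}\t{t}\t{s:.6f}\n")

    @classmethod
    def from_tsv(cls, path, mode: str = "S") -> "PredictionSet":
        scores: Dict[str, Dict[str, float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                p, t, s = line.split("\t")
                scores.setdefault(p, {})[t] = float(s)
        return cls(scores=scores, mode=mode)


def minmax_scale(values: Sequence[float], floor: float = DEFAULT_SCORE_FLOOR) -> List[float]:
    """Map values affinely onto (floor, 1]; a constant list maps to all 1."""
    if len(values) == 0:
        raise ValueError("cannot scale an empty list")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [1.0] * len(values)
    # the maximum maps to exactly 1.0 (scores must lie in (0, 1])
    return [
        1.0 if v == hi else floor + (1.0 - floor) * (v - lo) / (hi - lo)
        for v in values
    ]


def dag_consistency_pass(
    predictions: Dict[str, Dict[str, float]], dag: OntologyDag
) -> Dict[str, Dict[str, float]]:
    """Lift scores to ancestors: score(parent) = max(existing, child). Idempotent."""
    out: Dict[str, Dict[str, float]] = {}
    cache: Dict[str, Set[str]] = {}
    for protein, terms in predictions.items():
        lifted: Dict[str, float] = {}
        for term, score in terms.items():
            if term not in cache:
                cache[term] = dag.ancestors(term) | {term}
            for anc in cache[term]:
                if score > lifted.get(anc, 0.0):
                    lifted[anc] = score
        out[protein] = lifted
    return out


def predict_functions(
    mappings,
    protein_domains: Mapping[str, Set[str]],
    dag: Optional[OntologyDag] = None,
    score_mode: str = "S",
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> PredictionSet:
    """Propagate mappings to proteins, producing a scored prediction set.

    score_mode "S" uses the co-occurrence similarity column directly;
    "E" min-max scales the E column onto (floor, 1] first; "reference" sets
    every score to 1.0 (curated-mapping mode).  Passing a dag enables the
    ancestor consistency pass.
    """
    df = mappings.rows if hasattr(mappings, "rows") else mappings
    if len(df) == 0:
        raise ValueError("empty mapping table")
    if score_mode == "S":
        scores = df["s"].astype(float).tolist()
    elif score_mode == "E":
        if "e" not in df.columns:
            raise ValueError("E-mode prediction requires an 'e' column")
        scores = minmax_scale(df["e"].astype(float).tolist(), floor=score_floor)
    elif score_mode == "reference":
        scores = [1.0] * len(df)
    else:
        raise ValueError(f"unknown score mode {score_mode!r}")

    by_domain: Dict[str, List[Tuple[str, float]]] = {}
    for domain, term, score in zip(df["domain_id"], df["go_id"], scores):
        by_domain.setdefault(domain, []).append((term, score))

    preds: Dict[str, Dict[str, float]] = {}
    for protein, domains in protein_domains.items():
        terms: Dict[str, float] = {}
        for d in domains:
            for term, score in by_domain.get(d, ()):
                if score > terms.get(term, 0.0):
                    terms[term] = score
        if terms:
            preds[protein] = terms

    if dag is not None:
        preds = dag_consistency_pass(preds, dag)
    return PredictionSet(scores=preds, mode=score_mode)


def naive_baseline(
    train_go: Mapping[str, Set[str]], targets: Iterable[str]
) -> PredictionSet:
    """Frequency baseline: every target gets every training term, scored by
    the term's annotation frequency among training proteins."""
    train_go = dict(train_go)
    if not train_go:
        raise ValueError("empty training annotation set")
    total = len(train_go)
    freq: Dict[str, float] = {}
    for terms in train_go.values():
        for t in terms:
            freq[t] = freq.get(t, 0.0) + 1.0
    freq = {t: c / total for t, c in freq.items()}
    return PredictionSet(
        scores={p: dict(freq) for p in targets},
        mode="naive",
    )


def merge_hybrid(sets: Sequence[PredictionSet]) -> PredictionSet:
    """Max-merge several prediction sets: union of records, maximum score on
    duplicates. Associative, commutative, idempotent."""
    if len(sets) < 2:
        raise ValueError("hybrid merge needs at least two prediction sets")
    merged: Dict[str, Dict[str, float]] = {}
    for ps in sets:
        for protein, terms in ps.scores.items():
            slot = merged.setdefault(protein, {})
            for term, score in terms.items():
                if score > slot.get(term, 0.0):
                    slot[term] = score
    return PredictionSet(
        scores=merged,
        mode="hybrid",
        components=[ps.mode for ps in sets],
    )
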