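"""Top-K enrichment of a curated reference among ranked mappings.

Used for the ablation across ranking scores (S, theta_init, theta, E): rank
all mined pairs by one score, then compare the number of curated pairs
observed in the top K against the count expected under a uniform spread of
curated pairs across the whole ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Set, Tuple

import pandas as pd

Pair = Tuple[str, str]

SCORE_NAMES = ("s", "theta_init", "theta", "e")


@dataclass
class ReferenceMappingSet:
    """Curated (domain, GO) pairs serving as ground truth for enrichment."""

    pairs: Set[Pair]
    label: str = "curated"

    @classmethod
    def from_tsv(cls, path, label: str | None = None) -> "ReferenceMappingSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns[:2])
        return cls(
            pairs=set(zip(df[cols[0]], df[cols[1]])),
            label=label or str(path),
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EnrichmentCurve:
    ks: List[int]
    observed: List[int]
    expected: List[float]
    ratio: List[float]
    score_name: str = "s"
    reference_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.ks,
                "observed": self.observed,
                "expected": self.expected,
                "ratio": self.ratio,
                "score_name": self.score_name,
            }
        )


def rank_mappings(table, score_name: str) -> List[Tuple[str, str, float]]:
    """Rank (domain, GO) pairs by a score column, descending.

    Ties break deterministically: larger support n first, then lexicographic
    pair key.  ``table`` may be a MappingTable or a DataFrame carrying at
    least domain_id, go_id and the score column.
    """
    df = table.rows if hasattr(table, "rows") else table
    if score_name not in df.columns:
        raise ValueError(
            f"unknown score {score_name!r}; available: {sorted(df.columns)}"
        )
    cols = ["domain_id", "go_id", score_name] + (["n"] if "n" in df.columns else [])
    work = df[cols].copy()
    if "n" not in work.columns:
        work["n"] = 0
    work = work.sort_values(
        by=[score_name, "n", "domain_id", "go_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return list(zip(work["domain_id"], work["go_id"], work[score_name].astype(float)))


def enrichment_at_k(
    ranked: Sequence[Tuple[str, str, float]],
    reference: ReferenceMappingSet,
    ks: Iterable[int],
    score_name: str = "s",
) -> EnrichmentCurve:
    """Observed vs expected curated pairs in the top K of a ranked list.

    expected(K) = K * (curated pairs present anywhere in the list / list
    length); ratio = observed/expected.  A reference disjoint from the list
    makes every expectation zero and is rejected.
    """
    ranked = list(ranked)
    ks = sorted(set(int(k) for k in ks))
    if ks and ks[-1] > len(ranked):
        raise ValueError(f"K={ks[-1]} exceeds ranked list length {len(ranked)}")
    in_list = sum(1 for d, g, _ in ranked if (d, g) in reference.pairs)
    if in_list == 0:
        raise ValueError("expected enrichment is zero: reference disjoint from ranked list")
    frac = in_list / len(ranked)
    observed, expected, ratio = [], [], []
    hits = 0
    k_iter = iter(ks)
    next_k = next(k_iter, None)
    for rank, (d, g, _) in enumerate(ranked, start=1):
        if (d, g) in reference.pairs:
            hits += 1
        while next_k is not None and rank == next_k:
            observed.append(hits)
            exp = next_k * frac
            expected.append(exp)
            ratio.append(hits / exp)
            next_k = next(k_iter, None)
    return EnrichmentCurve(
        ks=ks,
        observed=observed,
        expected=expected,
        ratio=ratio,
        score_name=score_name,
        reference_label=reference.label,
    )
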