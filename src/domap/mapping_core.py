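"""Domain-to-GO mapping mining.

A domain D and a GO term G co-annotated on at least one shared protein form a
candidate mapping.  Each mapping carries a support count ``n`` (proteins
co-annotated with both), the marginal protein counts, and a Dice-type
co-occurrence similarity

    S = 2 * n / (N_D + N_G)

Reliability thresholds on (S, n) are selected by comparing the observed
S-distribution against a column-shuffled null with a two-sample
Kolmogorov-Smirnov test over a small candidate grid, choosing the lowest
(n, S) pair at which the null hypothesis of identical distributions is
rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import AnnotationCorpus

MAPPING_COLUMNS = ["domain_id", "go_id", "n", "n_domain", "n_go", "s"]

DEFAULT_S_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
DEFAULT_N_GRID = (1, 2, 3, 4, 5)
DEFAULT_ALPHA = 0.01


def cooccurrence_similarity(n_co: int, n_domain: int, n_go: int) -> float:
    """Dice-type overlap 2*n_co/(n_domain+n_go) of the two protein sets."""
    if not (1 <= n_co <= min(n_domain, n_go)):
        raise ValueError(
            f"invalid counts: n_co={n_co}, n_domain={n_domain}, n_go={n_go}"
        )
    return 2.0 * n_co / (n_domain + n_go)


@dataclass
class MappingTable:
    """Unique (domain, GO) rows with support and co-occurrence scores.

    ``triplets`` holds the underlying co-annotation evidence records
    (protein, domain, go) the table was computed from; randomization permutes
    those records and recomputes the table, so they travel together.
    """

    rows: pd.DataFrame
    provenance: str = "original"
    corpus_digest: str = ""
    triplets: Optional[pd.DataFrame] = None  # columns: protein_id, domain_id, go_id

    def __post_init__(self) -> None:
        if self.rows.duplicated(subset=["domain_id", "go_id"]).any():
            raise ValueError("duplicate (domain_id, go_id) pairs in mapping table")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def pairs(self) -> Set[Tuple[str, str]]:
        return set(zip(self.rows["domain_id"], self.rows["go_id"]))

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, provenance: str = "original") -> "MappingTable":
        return cls(rows=pd.read_csv(path, sep="\t", dtype={"domain_id": str, "go_id": str}),
                   provenance=provenance)


def _corpus_digest(corpus: AnnotationCorpus) -> str:
    h = hashlib.sha256()
    for p in sorted(corpus.protein_domains):
        h.update(p.encode())
        h.update(",".join(sorted(corpus.protein_domains[p])).encode())
    for p in sorted(corpus.protein_go):
        h.update(p.encode())
        h.update(",".join(sorted(corpus.protein_go[p])).encode())
    return h.hexdigest()[:16]


def _table_from_triplets(triplets: pd.DataFrame, provenance: str, digest: str) -> MappingTable:
    """Recompute per-pair n, marginals and S from co-annotation records."""
    n = (
        triplets.groupby(["domain_id", "go_id"], sort=True)["protein_id"]
        .nunique()
        .rename("n")
        .reset_index()
    )
    n_domain = triplets.groupby("domain_id")["protein_id"].nunique()
    n_go = triplets.groupby("go_id")["protein_id"].nunique()
    n["n_domain"] = n["domain_id"].map(n_domain)
    n["n_go"] = n["go_id"].map(n_go)
    n["s"] = 2.0 * n["n"] / (n["n_domain"] + n["n_go"])
    return MappingTable(rows=n[MAPPING_COLUMNS], provenance=provenance,
                        corpus_digest=digest, triplets=triplets)


def build_initial_mappings(corpus: AnnotationCorpus) -> MappingTable:
    """Enumerate every co-annotated (domain, GO) pair over shared proteins.

    Counts n, N_D and N_G over proteins present in both annotation maps; the
    marginals therefore refer to the same protein universe as the supports.
    """
    shared = sorted(corpus.shared_proteins())
    if not shared:
        raise ValueError("no protein is present in both annotation maps")

    records: List[Tuple[str, str, str]] = []
    for p in shared:
        for d in sorted(corpus.protein_domains[p]):
            for g in sorted(corpus.protein_go[p]):
                if g in corpus.roots:  # namespace roots are uninformative
                    continue
                records.append((p, d, g))
    triplets = pd.DataFrame(records, columns=["protein_id", "domain_id", "go_id"])
    return _table_from_triplets(triplets, "original", _corpus_digest(corpus))


def randomize_mappings(table: MappingTable, seed: int, unit: str = "triplet") -> MappingTable:
    """Column-shuffle null: permute the GO column and recompute S and n.

    ``unit="triplet"`` (default) permutes the GO column of the co-annotation
    evidence records and rebuilds the pair table, so the null preserves both
    per-column marginal multisets while supports are recomputable.
    ``unit="pair"`` permutes the GO column of the unique-pair table itself,
    keeping each row's original n.
    """
    if table.provenance != "original":
        raise ValueError("randomize_mappings expects an original-provenance table")
    rng = np.random.default_rng(seed)
    if unit == "triplet":
        if table.triplets is None:
            raise ValueError("triplet-level shuffle requires evidence triplets")
        shuffled = table.triplets.copy()
        perm = rng.permutation(len(shuffled))
        shuffled["go_id"] = shuffled["go_id"].to_numpy()[perm]
        return _table_from_triplets(shuffled, "randomized", table.corpus_digest)
    if unit == "pair":
        rows = table.rows.copy()
        perm = rng.permutation(len(rows))
        rows["go_id"] = rows["go_id"].to_numpy()[perm]
        rows["n_go"] = rows["n_go"].to_numpy()[perm]
        rows["s"] = 2.0 * rows["n"] / (rows["n_domain"] + rows["n_go"])
        rows = rows.drop_duplicates(subset=["domain_id", "go_id"])
        return MappingTable(rows=rows.reset_index(drop=True), provenance="randomized",
                            corpus_digest=table.corpus_digest)
    raise ValueError(f"unknown shuffle unit: {unit!r}")


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Uses the exact p-value when the combined sample size is below 10,000 and
    the asymptotic Kolmogorov distribution otherwise, for determinism at scale.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    method = "exact" if a.size + b.size < 10_000 else "asymp"
    result = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


@dataclass
class ThresholdSelection:
    """Outcome of the (S, n) grid scan.

    ``selected`` is the lowest passing (s_min, n_min) pair under the ordering
    ascending n then ascending S, or ``None`` with ``no_separation`` set when
    no grid cell rejects the null at ``alpha``.
    """

    grid: List[Tuple[float, int]]
    ks_results: Dict[Tuple[float, int], Tuple[float, float, int, int]]
    selected: Optional[Tuple[float, int]]
    alpha: float
    no_separation: bool = False
    untestable: List[Tuple[float, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (s_min, n_min) in self.grid:
            res = self.ks_results.get((s_min, n_min))
            rows.append(
                {
                    "s_min": s_min,
                    "n_min": n_min,
                    "statistic": res[0] if res else np.nan,
                    "p_value": res[1] if res else np.nan,
                    "n_original": res[2] if res else 0,
                    "n_randomized": res[3] if res else 0,
                    "testable": res is not None,
                    "selected": self.selected == (s_min, n_min),
                }
            )
        return pd.DataFrame(rows)


def select_thresholds(
    original: MappingTable,
    randomized: MappingTable,
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    alpha: float = DEFAULT_ALPHA,
) -> ThresholdSelection:
    """Scan the (S, n) candidate grid and pick the lowest significant pair.

    For each candidate, both tables are restricted to rows with s >= s_min and
    n >= n_min and the two filtered S-distributions are compared by KS; the
    first pair (ordered by ascending n_min, then s_min) with p < alpha wins.
    Cells that empty either table are recorded as untestable.
    """
    if not s_grid or not n_grid:
        raise ValueError("threshold grids must be non-empty")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")

    grid = [(float(s), int(n)) for n in sorted(n_grid) for s in sorted(s_grid)]
    ks_results: Dict[Tuple[float, int], Tuple[float, float, int, int]] = {}
    untestable: List[Tuple[float, int]] = []
    selected: Optional[Tuple[float, int]] = None

    for s_min, n_min in grid:
        orig = original.rows.loc[
            (original.rows["s"] >= s_min) & (original.rows["n"] >= n_min), "s"
        ]
        rand = randomized.rows.loc[
            (randomized.rows["s"] >= s_min) & (randomized.rows["n"] >= n_min), "s"
        ]
        if orig.empty or rand.empty:
            untestable.append((s_min, n_min))
            continue
        stat, pval = ks_two_sample(orig.to_numpy(), rand.to_numpy())
        ks_results[(s_min, n_min)] = (stat, pval, len(orig), len(rand))
        if selected is None and pval < alpha:
            selected = (s_min, n_min)

    return ThresholdSelection(
        grid=grid,
        ks_results=ks_results,
        selected=selected,
        alpha=alpha,
        no_separation=selected is None,
        untestable=untestable,
    )


def filter_mappings(table: MappingTable, s_min: float, n_min: int) -> MappingTable:
    """Final reliability filter: keep rows with n >= n_min and s strictly > s_min."""
    mask = (table.rows["n"] >= n_min) & (table.rows["s"] > s_min)
    rows = table.rows.loc[mask].reset_index(drop=True)
    trips = None
    if table.triplets is not None:
        keep = set(zip(rows["domain_id"], rows["go_id"]))
        tkeys = list(zip(table.triplets["domain_id"], table.triplets["go_id"]))
        trips = table.triplets.loc[[k in keep for k in tkeys]].reset_index(drop=True)
    return MappingTable(rows=rows, provenance=table.provenance,
                        corpus_digest=table.corpus_digest, triplets=trips)
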