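"""Readers for protein->domain and protein->GO annotation tables.

Two GO dialects are accepted: full GAF 2.1/2.2 (17 tab-separated columns,
``!`` comment lines) and a simplified 3-column table
``protein_id<TAB>go_id<TAB>evidence_code`` for readable fixtures; the dialect
is auto-detected from the column count.  Electronic (IEA) annotations are
excluded by default and NOT-qualified rows are always dropped, since a
negated annotation must not assert function.  All readers tolerate gzip.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Set

import pandas as pd

from .ontology_io import OntologyDag

DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})


class SchemaError(ValueError):
    """An input table lacks a required column."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class AnnotationCorpus:
    """Joint protein->domain and protein->GO corpus keyed by protein id.

    ``protein_go`` sets are ancestor-closed and keep the namespace roots;
    ``roots`` records them so the mapping stage can skip those uninformative
    terms.  The mapping stage uses only proteins present in both maps
    (:meth:`shared_proteins`).
    """

    protein_domains: Dict[str, Set[str]]
    protein_go: Dict[str, Set[str]]
    evidence_filter: frozenset = DEFAULT_EXCLUDED_EVIDENCE
    roots: Set[str] = field(default_factory=set)

    def shared_proteins(self) -> Set[str]:
        return set(self.protein_domains) & set(self.protein_go)

    def __len__(self) -> int:
        return len(set(self.protein_domains) | set(self.protein_go))


@dataclass
class LoadReport:
    """Counters from a GO annotation load, for provenance."""

    kept: int = 0
    excluded_evidence: int = 0
    excluded_not: int = 0
    excluded_obsolete: int = 0
    skipped_lines: int = 0
    resolved_alt_ids: int = 0


def read_domain_annotations(path, entry_type_filter: str = "Domain") -> Dict[str, Set[str]]:
    """Read a (protein_id, domain_id, entry_type) TSV, keeping one entry type.

    Mirrors restricting an InterPro protein-signature table to entries of type
    "Domain".  Duplicate rows collapse to set membership.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ("protein_id", "domain_id", "entry_type")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"domain annotation table missing column {col!r}")
    df = df[df["entry_type"] == entry_type_filter]
    out: Dict[str, Set[str]] = {}
    for protein, domain in zip(df["protein_id"], df["domain_id"]):
        out.setdefault(protein, set()).add(domain)
    return out


def _iter_gaf_rows(handle):
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        yield lineno, line.split("\t")


def read_go_annotations(
    path,
    dag: OntologyDag,
    excluded_evidence: Optional[Set[str]] = None,
    report: Optional[LoadReport] = None,
) -> Dict[str, Set[str]]:
    """Read protein->GO annotations from GAF or the simplified 3-column TSV.

    Rows with an excluded evidence code or a NOT qualifier are dropped;
    alt_ids resolve to primary terms; obsolete terms are dropped and counted.
    Returns the raw (un-propagated) map.  Pass a :class:`LoadReport` to
    collect exclusion counters.
    """
    if excluded_evidence is None:
        excluded_evidence = set(DEFAULT_EXCLUDED_EVIDENCE)
    if report is None:
        report = LoadReport()

    out: Dict[str, Set[str]] = {}
    with _open_text(path) as handle:
        for lineno, fields in _iter_gaf_rows(handle):
            if len(fields) >= 15:  # GAF 2.x
                protein, qualifier, go_id, evidence = (
                    fields[1],
                    fields[3],
                    fields[4],
                    fields[6],
                )
            elif len(fields) == 3:  # simplified dialect
                protein, go_id, evidence = fields
                qualifier = ""
            else:
                report.skipped_lines += 1
                continue
            if "NOT" in qualifier.split("|"):
                report.excluded_not += 1
                continue
            if evidence in excluded_evidence:
                report.excluded_evidence += 1
                continue
            resolved = dag.resolve(go_id)
            if resolved != go_id:
                report.resolved_alt_ids += 1
            if resolved not in dag.graph or resolved in dag.obsolete:
                report.excluded_obsolete += 1
                continue
            out.setdefault(protein, set()).add(resolved)
            report.kept += 1

    if not out:
        raise ValueError(f"no GO annotations survived filtering in {path!r}")
    return out


def propagate_go_annotations(
    annotations: Mapping[str, Set[str]], dag: OntologyDag
) -> Dict[str, Set[str]]:
    """Close each protein's GO set under is_a/part_of ancestors (idempotent)."""
    closure_cache: Dict[str, Set[str]] = {}
    out: Dict[str, Set[str]] = {}
    for protein, terms in annotations.items():
        closed: Set[str] = set()
        for t in terms:
            t = dag.resolve(t)
            if t not in closure_cache:
                closure_cache[t] = dag.ancestors(t) | {t}
            closed |= closure_cache[t]
        out[protein] = closed
    return out


def build_corpus(
    protein_domains: Mapping[str, Set[str]],
    protein_go: Mapping[str, Set[str]],
    dag: OntologyDag,
    propagate: bool = True,
    evidence_filter: frozenset = DEFAULT_EXCLUDED_EVIDENCE,
) -> AnnotationCorpus:
    """Assemble the joint corpus, propagating GO annotations unless told not to."""
    go = propagate_go_annotations(protein_go, dag) if propagate else dict(protein_go)
    return AnnotationCorpus(
        protein_domains={p: set(d) for p, d in protein_domains.items()},
        protein_go=go,
        evidence_filter=evidence_filter,
        roots=set(dag.roots.values()),
    )
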