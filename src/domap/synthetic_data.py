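"""Synthetic annotation corpora with planted domain-GO associations.

The generator emulates, at desk scale, the inputs of the mapping pipeline: a
small three-namespace GO-like DAG, protein->domain assignments, and
protein->GO annotations driven by a set of *planted* true domain->term
associations plus annotation noise and dropout.  A held-out fraction of
proteins plays the role of a no-knowledge benchmark: their GO annotations
are withheld from the training corpus and become evaluation truth.

Planted associations are injective in both coordinates (one domain maps to
at most one planted term and vice versa), so in a noise-free run every
planted pair reaches co-occurrence similarity 1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np

from .annotation_io import AnnotationCorpus, propagate_go_annotations
from .enrichment import ReferenceMappingSet
from .evaluation import BenchmarkSet
from .ontology_io import NAMESPACES, OntologyDag, parse_obo

Pair = Tuple[str, str]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a corpus small enough for seconds-scale runs yet large
    enough that planted associations dominate chance co-annotation: 500
    proteins carrying 1-3 of 50 domains, 100 terms in a depth-3 DAG, 30
    planted associations, 20% per-protein noise and 10% planted-term dropout.
    """

    n_proteins: int = 500
    n_domains: int = 50
    n_terms: int = 100
    dag_depth: int = 3
    planted: int = 30
    domains_per_protein: Tuple[int, int] = (1, 3)
    noise_rate: float = 0.2
    dropout_rate: float = 0.1
    benchmark_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.noise_rate, self.dropout_rate, self.benchmark_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.planted > self.n_domains * self.n_terms:
            raise ValueError("more planted pairs than possible (domain, term) pairs")
        if self.domains_per_protein[0] < 1:
            raise ValueError("each protein needs at least one domain")
        if self.n_terms < 3 * (self.dag_depth + 1):
            raise ValueError("too few terms for three namespaces of the requested depth")


@dataclass
class SyntheticTruth:
    """A generated corpus together with everything needed to judge recovery."""

    config: SyntheticConfig
    dag: OntologyDag
    corpus: AnnotationCorpus  # training corpus (held-out GO withheld)
    reference: ReferenceMappingSet  # the planted pairs, as a curated-style set
    benchmark: BenchmarkSet
    planted_pairs: Set[Pair] = field(default_factory=set)
    implied_pairs: Set[Pair] = field(default_factory=set)
    obo_text: str = ""
    direct_go: Dict[str, Set[str]] = field(default_factory=dict)  # pre-propagation
    heldout_proteins: Set[str] = field(default_factory=set)


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _build_obo(config: SyntheticConfig, rng: np.random.Generator) -> str:
    """Random layered DAG over three namespaces, serialized as OBO 1.2 text.

    Each namespace gets a root and ``dag_depth`` non-empty layers; every
    non-root term has one is_a parent in the layer above and, with
    probability 0.2, an extra part_of parent in any shallower layer.
    """
    per_ns = [config.n_terms // 3] * 3
    per_ns[0] += config.n_terms - sum(per_ns)

    stanzas: List[str] = ["format-version: 1.2\nontology: synthetic\n"]
    next_id = 1
    for ns_idx, ns in enumerate(NAMESPACES):
        count = per_ns[ns_idx]
        ids = [_term_id(next_id + k) for k in range(count)]
        next_id += count
        root = ids[0]
        rest = ids[1:]
        # round-robin into dag_depth layers so each layer is non-empty
        layers: List[List[str]] = [[] for _ in range(config.dag_depth)]
        for k, t in enumerate(rest):
            layers[k % config.dag_depth].append(t)
        layer_of: Dict[str, int] = {root: 0}
        parents: Dict[str, List[Tuple[str, str]]] = {}
        for depth, layer in enumerate(layers, start=1):
            above = [root] if depth == 1 else layers[depth - 2]
            shallower = [root] + [t for l in layers[: depth - 1] for t in l]
            for t in layer:
                layer_of[t] = depth
                primary = above[rng.integers(len(above))]
                parents[t] = [("is_a", primary)]
                if len(shallower) > 1 and rng.random() < 0.2:
                    extra = shallower[rng.integers(len(shallower))]
                    if extra != primary:
                        parents[t].append(("part_of", extra))

        for t in ids:
            lines = [f"[Term]", f"id: {t}", f"name: synthetic term {t[3:]}",
                     f"namespace: {ns}"]
            for rel, parent in parents.get(t, []):
                if rel == "is_a":
                    lines.append(f"is_a: {parent} ! parent")
                else:
                    lines.append(f"relationship: part_of {parent} ! parent")
            stanzas.append("\n".join(lines) + "\n")
    return "\n".join(stanzas)


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Build a corpus with planted associations; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    obo_text = _build_obo(config, rng)
    import io

    dag = parse_obo(io.StringIO(obo_text))
    roots = set(dag.roots.values())
    nonroot_terms = sorted(t for t in dag.terms if t not in roots)

    domains = [f"DOM{i:04d}" for i in range(1, config.n_domains + 1)]
    proteins = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]

    planted_domains = rng.choice(config.n_domains, size=config.planted, replace=False)
    # planted terms form an antichain (none is an ancestor of another), so in
    # a noise-free run propagation cannot inflate a planted term's marginal
    order = rng.permutation(len(nonroot_terms))
    planted_terms: List[str] = []
    blocked: Set[str] = set()
    for idx in order:
        t = nonroot_terms[idx]
        if t in blocked:
            continue
        anc = dag.ancestors(t)
        if anc & set(planted_terms):
            continue
        planted_terms.append(t)
        blocked |= anc | {t}
        if len(planted_terms) == config.planted:
            break
    if len(planted_terms) < config.planted:
        raise ValueError("DAG too shallow to plant an antichain of the requested size")
    planted_pairs: Set[Pair] = {
        (domains[d], t) for d, t in zip(planted_domains, planted_terms)
    }

    lo, hi = config.domains_per_protein
    protein_domains: Dict[str, Set[str]] = {}
    for p in proteins:
        k = int(rng.integers(lo, hi + 1))
        picks = rng.choice(config.n_domains, size=k, replace=False)
        protein_domains[p] = {domains[i] for i in picks}

    planted_by_domain: Dict[str, str] = {d: g for d, g in planted_pairs}
    direct_go: Dict[str, Set[str]] = {p: set() for p in proteins}
    for p in proteins:
        for d in sorted(protein_domains[p]):
            g = planted_by_domain.get(d)
            if g is not None and rng.random() >= config.dropout_rate:
                direct_go[p].add(g)
        if rng.random() < config.noise_rate:
            direct_go[p].add(nonroot_terms[int(rng.integers(len(nonroot_terms)))])
    direct_go = {p: ts for p, ts in direct_go.items() if ts}

    n_heldout = int(round(config.benchmark_fraction * len(proteins)))
    heldout = set(
        proteins[i]
        for i in rng.choice(config.n_proteins, size=n_heldout, replace=False)
    )

    train_go = {p: ts for p, ts in direct_go.items() if p not in heldout}
    propagated_train = propagate_go_annotations(train_go, dag)
    corpus = AnnotationCorpus(
        protein_domains={p: set(ds) for p, ds in protein_domains.items()},
        protein_go=propagated_train,
        roots=roots,
    )

    heldout_go = {p: ts for p, ts in direct_go.items() if p in heldout}
    propagated_heldout = propagate_go_annotations(heldout_go, dag)
    truth = {
        p: {t for t in ts if t not in roots}
        for p, ts in propagated_heldout.items()
    }
    benchmark = BenchmarkSet(truth=truth, namespace="all")

    implied: Set[Pair] = set()
    for d, g in planted_pairs:
        implied.add((d, g))
        for anc in dag.ancestors(g):
            implied.add((d, anc))

    return SyntheticTruth(
        config=config,
        dag=dag,
        corpus=corpus,
        reference=ReferenceMappingSet(pairs=set(planted_pairs), label="planted"),
        benchmark=benchmark,
        planted_pairs=planted_pairs,
        implied_pairs=implied,
        obo_text=obo_text,
        direct_go=direct_go,
        heldout_proteins=heldout,
    )


def write_fixture_bundle(truth: SyntheticTruth, directory) -> Dict[str, str]:
    """Write the corpus in standard formats plus a provenance manifest.

    Files: go.obo, annotations.gaf (training proteins, direct annotations),
    domains.tsv, reference.tsv, benchmark.tsv, manifest.json.  Returns the
    manifest (file -> sha256).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    (directory / "go.obo").write_text(truth.obo_text)

    gaf_lines = ["!gaf-version: 2.2"]
    aspect = {"molecular_function": "F", "biological_process": "P",
              "cellular_component": "C"}
    for p in sorted(truth.direct_go):
        if p in truth.heldout_proteins:
            continue
        for t in sorted(truth.direct_go[p]):
            ns = truth.dag.namespaces.get(t, "molecular_function")
            cols = ["SYN", p, p, "enables", t, "SYN:0000001", "EXP", "",
                    aspect[ns], "", "", "protein", "taxon:0", "20160901",
                    "SYN", "", ""]
            gaf_lines.append("\t".join(cols))
    (directory / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")

    dom_lines = ["protein_id\tdomain_id\tentry_type"]
    for p in sorted(truth.corpus.protein_domains):
        for d in sorted(truth.corpus.protein_domains[p]):
            dom_lines.append(f"{p}\t{d}\tDomain")
    (directory / "domains.tsv").write_text("\n".join(dom_lines) + "\n")

    ref_lines = ["domain_id\tgo_id"]
    for d, g in sorted(truth.reference.pairs):
        ref_lines.append(f"{d}\t{g}")
    (directory / "reference.tsv").write_text("\n".join(ref_lines) + "\n")

    bench_lines = ["protein_id\tgo_id"]
    for p in sorted(truth.benchmark.truth):
        for t in sorted(truth.benchmark.truth[p]):
            bench_lines.append(f"{p}\t{t}")
    (directory / "benchmark.tsv").write_text("\n".join(bench_lines) + "\n")

    manifest: Dict[str, object] = {"config": asdict(truth.config), "files": {}}
    for name in ("go.obo", "annotations.gaf", "domains.tsv", "reference.tsv",
                 "benchmark.tsv"):
        digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest  # type: ignore[index]
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {k: v for k, v in manifest["files"].items()}  # type: ignore[union-attr]
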