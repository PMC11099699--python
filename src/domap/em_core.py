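"""Expectation-maximization over domain-GO co-annotation triplets.

Every protein p co-annotated with domain D and term G contributes a triplet
(D, p, G) carrying a latent responsibility C_p in [0, 1]: did this pair, or a
competing co-annotated pair on the same protein, cause the co-annotation?
Per pair, M = sum_p C_p, K = sum_p (1 - C_p), and Z counts proteins carrying
exactly one of the two annotations.  The association probability is
theta = M / (M + K + Z), and the E-step responsibility is the noisy-OR share

    U(C_p) = theta_DG / (1 - prod_{(x,y) in A(p)} (1 - theta_xy))

where A(p) is the set of co-annotated pairs on p.  Because the pair itself
belongs to A(p), the denominator is at least theta_DG, so U stays in [0, 1].

The E score for a pair is a leave-one-out log likelihood ratio: the EM is
rerun with that pair's theta pinned to zero, giving a competitor-only matrix
theta-bar, and

    E = sum_{p co-annotated} log[ (1 - prod(1-theta)) / (1 - prod(1-theta_bar)) ]

measures how much better the co-annotations are explained with the pair than
by its competitors alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .annotation_io import AnnotationCorpus
from .mapping_core import MappingTable

Pair = Tuple[str, str]


@dataclass
class EmConfig:
    """Tunables of the EM fit.

    alpha, beta   pseudocounts on the likelihood exponents (default 0: the
                  plain maximum-likelihood reading).
    rel_tolerance relative log-likelihood improvement below which iteration
                  stops ("stops increasing noticeably").
    epsilon       floor for logs and noisy-OR denominators; floored events
                  are reported, never silent.
    e_score_iterations  fixed EM iterations per leave-one-out rerun.
    """

    alpha: float = 0.0
    beta: float = 0.0
    max_iterations: int = 150
    rel_tolerance: float = 1e-4
    epsilon: float = 1e-12
    e_score_iterations: int = 10

    def __post_init__(self) -> None:
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be positive")
        if not (0 < self.epsilon <= 1e-6):
            raise ValueError("epsilon must lie in (0, 1e-6]")


@dataclass
class TripletSet:
    """Co-annotation evidence in indexed form.

    ``pairs`` and ``proteins`` are sorted for deterministic iteration;
    ``triplet_pair`` / ``triplet_protein`` index into them, one entry per
    (domain, protein, go) triplet.
    """

    pairs: List[Pair]
    proteins: List[str]
    triplet_pair: np.ndarray
    triplet_protein: np.ndarray
    pair_index: Dict[Pair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pair_index:
            self.pair_index = {p: i for i, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.triplet_pair)

    @property
    def triplets(self) -> List[Tuple[str, str, str]]:
        return [
            (self.pairs[j][0], self.proteins[i], self.pairs[j][1])
            for j, i in zip(self.triplet_pair, self.triplet_protein)
        ]

    def per_protein_pairs(self) -> Dict[str, Set[Pair]]:
        out: Dict[str, Set[Pair]] = {p: set() for p in self.proteins}
        for j, i in zip(self.triplet_pair, self.triplet_protein):
            out[self.proteins[i]].add(self.pairs[j])
        return out

    def pair_support(self) -> np.ndarray:
        """Number of co-annotated proteins per pair (the mapping support n)."""
        return np.bincount(self.triplet_pair, minlength=len(self.pairs)).astype(float)


def build_triplets(
    corpus: AnnotationCorpus, restrict_to: Optional[MappingTable] = None
) -> TripletSet:
    """Enumerate (domain, protein, go) co-annotation triplets.

    ``restrict_to`` limits which (domain, go) pairs generate triplets, e.g. a
    support-filtered mapping table when the full pair set is too large.
    """
    allowed: Optional[Set[Pair]] = restrict_to.pairs if restrict_to is not None else None
    shared = sorted(corpus.shared_proteins())
    pair_set: Set[Pair] = set()
    records: List[Tuple[Pair, str]] = []
    for p in shared:
        for d in sorted(corpus.protein_domains[p]):
            for g in sorted(corpus.protein_go[p]):
                if g in corpus.roots:
                    continue
                pair = (d, g)
                if allowed is not None and pair not in allowed:
                    continue
                pair_set.add(pair)
                records.append((pair, p))
    pairs = sorted(pair_set)
    pair_index = {pr: i for i, pr in enumerate(pairs)}
    protein_index = {p: i for i, p in enumerate(shared)}
    return TripletSet(
        pairs=pairs,
        proteins=shared,
        triplet_pair=np.array([pair_index[pr] for pr, _ in records], dtype=np.int64),
        triplet_protein=np.array([protein_index[p] for _, p in records], dtype=np.int64),
        pair_index=pair_index,
    )


@dataclass
class ThetaMatrix:
    """Association probabilities and sufficient statistics per pair.

    M + K equals the co-annotated protein count n at every iteration (each
    responsibility C_p lies in [0, 1] and K = sum(1 - C_p)); Z depends only
    on the corpus and never changes.
    """

    pairs: List[Pair]
    theta_arr: np.ndarray
    m_arr: np.ndarray
    k_arr: np.ndarray
    z_arr: np.ndarray
    n_arr: np.ndarray
    log_likelihood_trace: List[float] = field(default_factory=list)
    floored_proteins: int = 0
    pair_index: Dict[Pair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pair_index:
            self.pair_index = {p: i for i, p in enumerate(self.pairs)}

    @property
    def theta(self) -> Dict[Pair, float]:
        return {p: float(v) for p, v in zip(self.pairs, self.theta_arr)}

    @property
    def counts(self) -> Dict[Pair, Tuple[float, float, int]]:
        return {
            p: (float(m), float(k), int(z))
            for p, m, k, z in zip(self.pairs, self.m_arr, self.k_arr, self.z_arr)
        }

    def copy(self) -> "ThetaMatrix":
        return ThetaMatrix(
            pairs=self.pairs,
            theta_arr=self.theta_arr.copy(),
            m_arr=self.m_arr.copy(),
            k_arr=self.k_arr.copy(),
            z_arr=self.z_arr,
            n_arr=self.n_arr,
            log_likelihood_trace=list(self.log_likelihood_trace),
            floored_proteins=self.floored_proteins,
            pair_index=self.pair_index,
        )


def initialize_theta(triplets: TripletSet, corpus: AnnotationCorpus) -> ThetaMatrix:
    """Start from all responsibilities = 1: M = n, K = 0, theta = n/(n+Z).

    Z for a pair is the count of shared-corpus proteins carrying the domain
    without the term plus those carrying the term without the domain, so the
    initial theta equals the Jaccard index of the two protein sets.
    """
    shared = set(corpus.shared_proteins())
    domain_count: Dict[str, int] = {}
    go_count: Dict[str, int] = {}
    for p in shared:
        for d in corpus.protein_domains[p]:
            domain_count[d] = domain_count.get(d, 0) + 1
        for g in corpus.protein_go[p]:
            go_count[g] = go_count.get(g, 0) + 1

    n_arr = triplets.pair_support()
    z_arr = np.array(
        [
            (domain_count[d] - n_arr[i]) + (go_count[g] - n_arr[i])
            for i, (d, g) in enumerate(triplets.pairs)
        ],
        dtype=float,
    )
    m_arr = n_arr.copy()
    k_arr = np.zeros_like(n_arr)
    theta = m_arr / (m_arr + k_arr + z_arr)
    return ThetaMatrix(
        pairs=triplets.pairs,
        theta_arr=theta,
        m_arr=m_arr,
        k_arr=k_arr,
        z_arr=z_arr,
        n_arr=n_arr,
    )


def log_likelihood(matrix: ThetaMatrix, config: EmConfig) -> float:
    """Sum over pairs of (M+alpha) log theta + (K+Z+beta) log(1-theta), floored."""
    eps = config.epsilon
    t = np.clip(matrix.theta_arr, eps, 1.0 - 0.0)
    one_minus = np.maximum(1.0 - matrix.theta_arr, eps)
    return float(
        np.sum((matrix.m_arr + config.alpha) * np.log(t))
        + np.sum((matrix.k_arr + matrix.z_arr + config.beta) * np.log(one_minus))
    )


def _noisy_or_per_protein(
    theta: np.ndarray, triplets: TripletSet, eps: float
) -> Tuple[np.ndarray, int]:
    """1 - prod_{A(p)}(1 - theta) per protein, floored at eps.

    Returns the floored array and the number of proteins that hit the floor.
    """
    with np.errstate(divide="ignore"):
        log1m = np.log(np.maximum(1.0 - theta, 1e-300))
    acc = np.zeros(len(triplets.proteins))
    np.add.at(acc, triplets.triplet_protein, log1m[triplets.triplet_pair])
    denom = 1.0 - np.exp(acc)
    floored = int(np.sum(denom < eps))
    return np.maximum(denom, eps), floored


def em_iterate(
    matrix: ThetaMatrix,
    triplets: TripletSet,
    config: EmConfig,
    pinned_zero: Optional[Pair] = None,
) -> ThetaMatrix:
    """One full EM iteration (E-step responsibilities, then M-step re-estimate).

    With ``pinned_zero``, that pair's theta is forced to zero before the
    E-step (and reported as zero), yielding the leave-one-out model.
    """
    theta = matrix.theta_arr.copy()
    pin_idx = None
    if pinned_zero is not None:
        pin_idx = matrix.pair_index[pinned_zero]
        theta[pin_idx] = 0.0

    denom, floored = _noisy_or_per_protein(theta, triplets, config.epsilon)
    u = theta[triplets.triplet_pair] / denom[triplets.triplet_protein]
    u = np.clip(u, 0.0, 1.0)

    m_new = np.zeros(len(matrix.pairs))
    np.add.at(m_new, triplets.triplet_pair, u)
    k_new = matrix.n_arr - m_new
    theta_new = m_new / (m_new + k_new + matrix.z_arr)
    if pin_idx is not None:
        theta_new[pin_idx] = 0.0

    matrix.theta_arr = theta_new
    matrix.m_arr = m_new
    matrix.k_arr = k_new
    matrix.floored_proteins += floored
    matrix.log_likelihood_trace.append(log_likelihood(matrix, config))
    return matrix


def run_em(
    triplets: TripletSet,
    corpus: AnnotationCorpus,
    config: Optional[EmConfig] = None,
    pinned_zero: Optional[Pair] = None,
    fixed_iterations: Optional[int] = None,
) -> ThetaMatrix:
    """Iterate EM from the all-associated initialization until convergence.

    Stops when the relative log-likelihood improvement falls below
    ``rel_tolerance`` or ``max_iterations`` is reached; ``fixed_iterations``
    overrides both (used by the leave-one-out reruns).
    """
    config = config or EmConfig()
    matrix = initialize_theta(triplets, corpus)
    if pinned_zero is not None:
        matrix.theta_arr[matrix.pair_index[pinned_zero]] = 0.0
    matrix.log_likelihood_trace.append(log_likelihood(matrix, config))

    limit = fixed_iterations if fixed_iterations is not None else config.max_iterations
    for _ in range(limit):
        prev = matrix.log_likelihood_trace[-1]
        em_iterate(matrix, triplets, config, pinned_zero=pinned_zero)
        current = matrix.log_likelihood_trace[-1]
        if not np.isfinite(current):
            raise ArithmeticError("EM log-likelihood became non-finite")
        if fixed_iterations is None:
            rel = abs(current - prev) / max(abs(prev), config.epsilon)
            if rel < config.rel_tolerance:
                break
    return matrix


@dataclass
class EvidenceTable:
    """Leave-one-out log likelihood-ratio evidence per pair.

    ``capped`` lists pairs whose ratio denominator hit the epsilon floor for
    at least one protein (typically pairs with no competitors, whose
    competitor-only model assigns the co-annotation probability ~0).
    """

    e: Dict[Pair, float]
    capped: Set[Pair] = field(default_factory=set)

    def __getitem__(self, pair: Pair) -> float:
        return self.e[pair]


def compute_e_scores(
    matrix: ThetaMatrix,
    triplets: TripletSet,
    corpus: AnnotationCorpus,
    config: Optional[EmConfig] = None,
    pairs: Optional[Sequence[Pair]] = None,
) -> EvidenceTable:
    """E score per pair via a pinned-to-zero EM rerun.

    The numerator noisy-OR uses the converged full-model theta; the
    denominator uses the competitor-only theta-bar from a fresh EM run of
    ``e_score_iterations`` iterations with the pair pinned.  Only proteins
    co-annotated with the pair contribute.
    """
    config = config or EmConfig()
    if pairs is None:
        pairs = matrix.pairs
    eps = config.epsilon

    full_or, _ = _noisy_or_per_protein(matrix.theta_arr, triplets, eps)

    # protein indices co-annotated with each pair
    proteins_of_pair: Dict[int, List[int]] = {}
    for j, i in zip(triplets.triplet_pair, triplets.triplet_protein):
        proteins_of_pair.setdefault(int(j), []).append(int(i))

    e: Dict[Pair, float] = {}
    capped: Set[Pair] = set()
    for pair in pairs:
        idx = matrix.pair_index[pair]
        pinned = run_em(
            triplets, corpus, config, pinned_zero=pair,
            fixed_iterations=config.e_score_iterations,
        )
        with np.errstate(divide="ignore"):
            log1m = np.log(np.maximum(1.0 - pinned.theta_arr, 1e-300))
        acc = np.zeros(len(triplets.proteins))
        np.add.at(acc, triplets.triplet_protein, log1m[triplets.triplet_pair])
        pinned_or = 1.0 - np.exp(acc)
        prots = proteins_of_pair.get(idx, [])
        if np.any(pinned_or[prots] < eps):
            capped.add(pair)
        pinned_or = np.maximum(pinned_or, eps)
        e[pair] = float(np.sum(np.log(full_or[prots] / pinned_or[prots])))
    return EvidenceTable(e=e, capped=capped)
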