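# Methods

## The association model

The unit of evidence is the **co-annotation triplet** (domain D, protein p,
GO term G): protein p carries domain D and is annotated with term G after
ancestor propagation. Pairs (D, G) with at least one triplet form the
initial mapping table. Throughout, marginal counts N(D) and N(G) are taken
over the proteins present in both annotation maps, so supports and marginals
refer to the same universe; the three namespace roots are excluded from the
mapping step because every annotated protein carries them.

**Co-occurrence similarity.** S = 2·N(D,G)/(N(D)+N(G)) — the Dice overlap of
the two protein sets. S = 1 iff the sets coincide; for fixed N(D)+N(G) it is
strictly increasing in the support n = N(D,G).

**Null model.** The GO column of the triplet list is permuted uniformly at
random and the pair table (n, marginals, S) recomputed from the shuffled
records. Shuffling at the record level (rather than on the unique-pair
table) is what makes n recomputable and preserves both per-column marginal
multisets exactly; the derived unique-pair table may change row count
because collisions merge. A pair-level shuffle (GO column of the unique-pair
table permuted, original n kept, collided rows deduplicated) is available as
`unit="pair"`. Only one column is permuted: permuting one side of a
bipartite pairing is distributionally equivalent to permuting both
independently. A single shuffle is used, matching the resampling design the
thresholding is built on, rather than replicate-based empirical p-values.

**Threshold selection.** For each candidate cell (S ≥ s, n ≥ k) with
s ∈ {0.1,…,0.6}, k ∈ {1,…,5}, both tables are filtered and their
S-distributions compared with the two-sided two-sample Kolmogorov–Smirnov
test (exact p-value below 10,000 combined samples, asymptotic above, for
determinism at scale). Cells that empty either table are untestable, not
errors. The selected cell is the first with p < α (default 0.01) in the
ordering ascending n, then ascending S — support count is treated as the
primary reliability axis. The final filter keeps rows with n ≥ k and
**strictly** S > s: the scan is inclusive (it measures lower-bound bins) but
the safety filter is strict.

**Safety margin.** A threshold selected at the very bottom of its candidate
grid only says that the boundary cell already separates; as a conservative
margin, any selected value equal to its grid minimum is moved one grid step
up before filtering. On the default synthetic corpus the scan selects
(S ≥ 0.1, n ≥ 1) and the applied thresholds become (S > 0.2, n ≥ 2). If no
cell separates, fallback thresholds (0.2, 2) are applied and flagged.

## EM and the E score

Responsibilities C_p ∈ [0,1] say whether pair (D,G) caused the co-annotation
on protein p. With A(p) the set of co-annotated pairs on p:

- initialization: all C_p = 1, so M = n, K = 0, and with Z = proteins
  carrying exactly one of the two annotations, θ_init = n/(n+Z) — exactly
  the Jaccard index of the two protein sets;
- E-step: U(C_p) = θ_DG / (1 − Π_{(x,y)∈A(p)} (1−θ_xy)). Because (D,G) is
  itself in A(p), the noisy-OR denominator is ≥ θ_DG, so U ≤ 1 by
  construction (clipped and asserted);
- M-step: M = Σ C_p, K = Σ (1−C_p) = n − M, θ = M/(M+K+Z). Z depends only
  on the corpus and never changes; M + K = n is conserved at every
  iteration;
- stopping: the log-likelihood Σ (M+α)·log θ + (K+Z+β)·log(1−θ) is tracked
  per iteration and iteration stops when its relative improvement falls
  below `rel_tolerance` or at `max_iterations`.

The likelihood exponents are read as (M+α) and (K+Z+β) with pseudocounts
α = β = 0 by default, and the E-step as the quotient above; these are the
internally consistent readings — the quotient is the only form that keeps
U a responsibility weight in [0,1], and it matches the earlier
Deng-style EM formulations for association mining that this model follows.

**E score.** For each pair, the EM is rerun from initialization for
`e_score_iterations` (default 10) fixed iterations with that pair's θ pinned
to zero before every E-step, giving the competitor-only matrix θ̄. Then

E = Σ_{p : (D,G) ∈ A(p)} log [ (1 − Π(1−θ)) / (1 − Π(1−θ̄)) ],

both products over A(p). A pair whose proteins carry no competing pairs has
a competitor-only co-annotation probability of ~0; the denominator is then
floored at ε and the pair reported in `capped` (its E is log(θ/ε)) rather
than silently clamped. Because the leave-one-out rerun costs one EM per
pair, E computation is restricted by default to pairs with S ≥ 0.1
(`restrict_s_min`), which at desk scale keeps the whole EM stage around a
second; the restriction is a first-class parameter.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `s_grid`, `n_grid` | 0.1–0.6 / 1–5 | candidate threshold cells (30 combinations) |
| `alpha` (KS) | 0.01 | significance level for the scan |
| `em_alpha`, `em_beta` | 0.0 | likelihood pseudocounts |
| `max_iterations` | 150 | EM cap ("stops increasing noticeably" guard) |
| `rel_tolerance` | 1e-4 | relative log-likelihood improvement cutoff |
| `epsilon` | 1e-12 | floor for logs and noisy-OR denominators |
| `e_score_iterations` | 10 | EM iterations per leave-one-out rerun |
| `restrict_s_min` | 0.1 | pair subset for the EM / E stage |
| score floor (E-mode) | 0.01 | lower edge of the min-max scaled range |
| τ grid | 0.01…1.00 | 100 evaluation thresholds |

## Prediction and evaluation conventions

A protein inherits every term mapped to any of its domains; when several
domains support one term the **maximum** score wins (consistent with the
hybrid max-merge rule; noisy-OR combination would change score semantics).
A DAG-consistency pass then lifts each score to all ancestors as
max(existing, child), since protein-centric evaluation assumes parent
scores dominate; the pass is idempotent. E-mode scores are min-max scaled
onto (0.01, 1] with the maximum mapped to exactly 1. The Naive baseline
assigns every training term its annotation frequency, identically for all
targets; curated reference mappings predict with score 1.0.

Precision at threshold τ averages TP/(TP+FP) over the m(τ) proteins with at
least one prediction at that threshold (thresholds with m(τ) = 0 are
skipped, not scored 0); recall averages TP/(TP+FN) over all benchmark
proteins (full mode) or over predicted proteins only (partial mode). These
are the standard protein-centric definitions; some renderings transpose the
FP/FN symbols between the two formulas, which we treat as a typesetting
artifact. Namespace roots are removed from both sides before scoring.
Fmax ties resolve to the smallest τ.

**Information content** is marginal-frequency IC: ic(t) = −log2 of the
fraction of annotated proteins carrying t among proteins annotated in t's
namespace, computed per namespace from the propagated training corpus
(ic(root) = 0; monotone non-decreasing from parent to child). Terms unseen
in the corpus are smoothed to the maximum observed IC of their namespace,
which keeps Smin finite while preserving ranking. Whether IC should be
per-namespace or global is genuinely open; per-namespace is used and
recorded here. Smin averages ru and mi over all benchmark proteins.

## The synthetic generator

`synthetic_data.generate` emulates the pipeline's inputs at desk scale:
a three-namespace layered DAG (each namespace a root plus `dag_depth`
non-empty layers; one is_a parent per term, an extra part_of parent with
probability 0.2); proteins carrying 1–3 of 50 domains; 30 planted
domain→term associations, injective in both coordinates and with the
planted terms an antichain (no planted term an ancestor of another), so a
noise-free run gives every planted pair S = 1. Proteins carrying a planted
domain receive its term with probability 1 − dropout (default 0.9); each
protein gains one uniformly random spurious term with probability
`noise_rate` (default 0.2). 20% of proteins are held out as a no-knowledge
benchmark: their GO annotations are withheld from training and become
evaluation truth. All outputs are deterministic under the seed, and the
bundle writer emits standard formats (OBO, GAF 2.2, TSV) so the generator
doubles as the integration tests' upstream.

Defaults (500 proteins / 50 domains / 100 terms / 30 planted / noise 0.2 /
dropout 0.1) are the study conditions used by the tests and the acceptance
script. The 1–3 domains-per-protein range mirrors the 2–3 domain average of
real proteomes and keeps the EM non-trivial (competing pairs share
proteins).

What the generator does *not* emulate: realistic GO topology (term counts
per namespace, fan-out, depth 10+), evidence-code heterogeneity, the heavy
tail of domain promiscuity, and protein sequences. Passing tests therefore
demonstrate correctness of the statistics and the pipeline mechanics, not
performance on real UniProt/InterPro snapshots.

## Known limitations

- **Cross-domain leakage at small corpus size.** With multi-domain proteins,
  a domain that happens to co-occur with a planted domain on a few proteins
  acquires genuine support for the planted term (and its ancestors): at 500
  proteins these chance pairs reach n of 2–8 and S of 0.2–0.45, and the
  (S, n) filter keeps roughly one spurious pair per ten survivors. The
  effect is a small-sample property — relative chance co-occurrence of this
  magnitude vanishes at database scale — but it bounds how clean the
  filtered set can be on desk-scale corpora. The EM stage separates these
  sharply (mean θ ≈ 0.76 for planted vs ≈ 0.006 for other pairs on the
  default corpus), which is exactly the role of θ and E in the full method.
- Recovery accounting treats a surviving (domain, ancestor-of-planted-term)
  pair as implied rather than spurious: propagation makes those pairs true
  consequences of the planted signal.
- The KS scan tests S-distributions only (not the joint (S, n) law), since
  the thresholding procedure it feeds is defined on S histograms.
- Single shuffle, single null: no FDR control across the 30 grid cells.
- Obsolete terms are rejected at load with counters; alt_ids resolve to
  primary IDs. Cross-ontology links, regulates-edges and taxon constraints
  are out of scope.
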