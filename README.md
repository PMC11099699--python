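# domap

Mining **domain → GO term associations** from co-annotation patterns, and
using them to predict protein function.

Protein domains are the structural and evolutionary units that carry
molecular function, but most functional knowledge is curated at the level of
whole proteins. `domap` recovers domain-level function by statistics alone:
if a domain and a GO term keep appearing on the same proteins, the pair is a
candidate association; the package separates real associations from
co-annotation coincidence, then propagates the surviving mappings back to
proteins as scored function predictions and evaluates them with the
protein-centric CAFA protocol.

## The method

Given protein→domain annotations and propagated protein→GO annotations
sharing a protein-ID key space:

1. **Co-occurrence similarity.** Every co-annotated pair (D, G) is scored
   with a Dice-type overlap of its protein sets,

   S(D,G) = 2·N(D,G) / (N(D) + N(G)),

   where N(D,G) counts proteins carrying both, and the support n = N(D,G)
   serves as a second reliability axis.

2. **Randomized null + KS thresholding.** The GO column of the co-annotation
   records is shuffled and S recomputed, giving the score distribution of
   chance pairings. A grid of candidate thresholds (S ≥ 0.1…0.6 × n ≥ 1…5)
   is scanned with the two-sample Kolmogorov–Smirnov test; the lowest
   (n, S) cell at which the real and null S-distributions separate
   (p < 0.01) sets the reliability filter (boundary cells are moved one
   grid step up as a conservative margin).

3. **EM association probabilities.** Each co-annotation triplet
   (D, protein, G) carries a latent responsibility: did this pair, or a
   competing co-annotated pair on the same protein, cause the observation?
   Expectation-maximization over all triplets yields a per-pair association
   probability θ, initialized at the Jaccard index of the two protein sets.

4. **E scores.** A leave-one-out log likelihood ratio: the EM is rerun with
   the pair's θ pinned to zero, and E sums, over the pair's proteins, the
   log-ratio of the noisy-OR co-annotation probabilities with and without
   the pair. High E means the pair itself — not its competitors — explains
   the data.

5. **Prediction & evaluation.** Proteins inherit the GO terms of their
   domains (score = S, or min-max-scaled E), scores are lifted to ancestor
   terms, and predictions are scored against a held-out benchmark with
   Fmax, Smin and coverage, in full and partial evaluation modes.

A synthetic-corpus generator with *planted* associations, annotation noise
and dropout makes every stage testable end to end without downloads.

## Worked example

```python
from domap import CooccurrenceMapper, DomainFunctionPredictor, evaluate
from domap.ontology_io import compute_information_content
from domap.synthetic_data import SyntheticConfig, generate

truth = generate(SyntheticConfig(seed=1))          # 500 proteins, 30 planted pairs
mapper = CooccurrenceMapper(random_state=1).fit(truth.corpus)
print(mapper.s_min_, mapper.n_min_, len(mapper.filtered_table_))

predictor = DomainFunctionPredictor(dag=truth.dag).fit(mapper.filtered_table_)
targets = {p: truth.corpus.protein_domains[p] for p in truth.benchmark.truth}
preds = predictor.predict(targets)
ic = compute_information_content(truth.dag, truth.corpus.protein_go)
res = evaluate(preds, truth.benchmark, ic=ic, mode="full", dag=truth.dag)
print(f"Fmax={res.fmax:.3f}  Smin={res.smin:.3f}  coverage={res.coverage:.3f}")
```

prints

```
0.2 2 82
Fmax=0.906  Smin=2.033  coverage=0.963
```

— the KS scan lands on the thresholds n ≥ 2, S > 0.2; 82 of 1405 initial
mappings survive; propagating them to the 100 held-out benchmark proteins
recovers their functions at Fmax ≈ 0.91 while covering 96% of them.

The same pipeline is available from a shell:

```bash
domap simulate --seed 1 --out bundle/
domap run --obo bundle/go.obo --gaf bundle/annotations.gaf \
          --domains bundle/domains.tsv --benchmark bundle/benchmark.tsv \
          --seed 1 --out run/
```

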