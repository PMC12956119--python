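# retell

Automated scoring of how stories change as people retell them.

In repeated-reproduction studies of narrative memory, a participant reads or
hears a story and then recalls it in writing over several days; in
serial-reproduction designs the output of one teller becomes the input of the
next. Quantifying how much of a story survives — and how similar different
people's versions become — traditionally requires slow, subjective human
rating. `retell` provides an automated, deterministic story-similarity
measure and the analysis machinery around it: retelling-lineage evolution
metrics, cross-participant dispersion analysis, and a synthetic
serial-reproduction corpus generator so the whole pipeline can be exercised
and validated without any external data.

It is aimed at researchers in memory, psycholinguistics, and cultural
transmission who work with free-recall transcripts.

## The measure

Sentences act as the unit of narrative events. For two stories *A* and *B*:

**Content.** Each sentence *i* of *A* gets a threshold
θᵢ = max\_{j≠i} sim(Aᵢ, Aⱼ), the most similar sentence *i* is to any *other*
sentence of its own story. Sentence *i* is **Remembered** in *B* iff its best
match there satisfies maxⱼ sim(Aᵢ, Bⱼ) > θᵢ — a candidate no closer than A's
internal redundancy likely depicts a different occurrence and counts as
**Forgotten**. Content similarity is the remembered fraction, averaged over
both directions:

    content(A, B) = ½ [ #remembered(A→B)/|A| + #remembered(B→A)/|B| ] ∈ [0, 1]

**Sequence.** Every sentence of *A* is mapped to its best match in *B* (no
threshold; ties to the lowest index; a target sentence may match several
sources), and Spearman's ρ is computed between the source positions 1..|A|
and the matched positions, again averaged over both directions:

    sequence(A, B) = ½ [ ρ(A→B) + ρ(B→A) ] ∈ [−1, 1]

**Combined.** `combined = content × sequence ∈ [−1, 1]`: high only when both
the events and their order survive; −1 for a perfectly reversed retelling.

Sentence similarity `sim` is pluggable: a deterministic lexical backend
(Jaccard index over token sets) and a word-vector backend (cosine of averaged
word vectors, any word2vec-format text table) share one contract.

On top of the pairwise score sit three per-participant trajectories
(**stabilization**: adjacent days; **consistency**: each day vs. the final
retelling; **modification**: the stimulus vs. each day), and a group-level
convergence analysis: all-pairs similarity → distance (d = 1 − s) →
2-D multidimensional scaling → per-condition **Standard Distance Deviation**

    SDD = √( Σᵢ [(xᵢ − x̄)² + (yᵢ − ȳ)²] / N )

with label-shuffle permutation tests for condition contrasts.

## Worked example

```python
from retell import *

# score two retellings of the same story
a = Story("day1", "p01", "coherent", 1,
          raw_text="", sentences=["the cat sat.", "the dog ran.", "birds sing loudly."])
b = Story("day2", "p01", "coherent", 2,
          raw_text="", sentences=["the cat sat.", "birds sing loudly."])
res = story_similarity(a, b, LexicalBackend())
print(f"content  = {res.content:.4f}  (A->B {res.content_ab:.4f}, B->A {res.content_ba:.4f})")
print(f"sequence = {res.sequence:.4f}  (A->B {res.sequence_ab:.4f}, B->A {res.sequence_ba:.4f})")
print(f"combined = {res.combined:.4f}")

# simulate a 20-participant convergence study and test day-5 dispersion
config, conditions = convergence_scenario()
lineages = generate_corpus(config, 20, conditions, seed=42)
day5 = [ln.story_on(5) for ln in lineages]
coords = embed_2d(similarity_to_distance(all_pairs_matrix(day5, LexicalBackend())))
test = dispersion_permutation_test(coords, [s.condition for s in day5],
                                   n_perm=999, seed=42)
for name, sdd in test.sdd.items():
    print(f"SDD[{name}] = {sdd:.3f}")
print(f"delta = {test.observed_difference:+.3f}, p = {test.p_value:.3f}")
```

Output:

```
content  = 0.8333  (A->B 0.6667, B->A 1.0000)
sequence = 0.9330  (A->B 0.8660, B->A 1.0000)
combined = 0.7775
SDD[convergent] = 0.250
SDD[drifting] = 0.447
delta = -0.197, p = 0.001
```

Story B dropped one of A's three events (directional content 2/3 one way, 1
the other) and kept the surviving order (sequence near 1), giving a combined
score of 0.78. In the simulated study, retellings biased toward a shared
event order (`convergent`) cluster much more tightly by day 5 than freely
drifting ones — a smaller SDD, significant under label permutation.

The same pipeline is available from a shell:

```sh
retell simulate   --config study.yaml --out corpus/
retell similarity --manifest corpus/manifest.csv --day 5 --out scores/
retell evolve     --manifest corpus/manifest.csv --out evolution/
retell dispersion --manifest corpus/manifest.csv --day 5 --out dispersion/
```

Real transcripts are consumed through the same manifest format
(`participant_id,condition,day,path` plus UTF-8 text files); cleaning removes
hedging meta-commentary ("if I remember correctly", …) before segmentation.

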