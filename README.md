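# egowords

**Concentric frequency layers of personal vocabulary and the semantics of
their rings.**

People do not use their words uniformly: a handful of lemmas carry most of a
person's written output, and usage frequency falls off in a long Zipf-like
tail.  `egowords` analyses this structure per user, borrowing the
concentric-circle model of personal social networks.  Given a user's tweet
timeline over a fixed observation window `T`, each lemma's frequency
`f = n/T` is log-transformed and clustered by one-dimensional mode-seeking
(Gaussian-kernel mean shift); the resulting frequency-ranked clusters are
the *rings* of that user's **ego network of words**, with layer `i` the
union of rings `1..i` and scaling ratio `rho_i = |L_i|/|L_{i-1}|`.

Given per-tweet topic assignments (the output of any external
embedding + clustering stage, ingested as hard or soft rows), the package
computes each ring's **semantic profile**

    P_r(c) = sum_{w in ring r} P_{m(w)}(c)  /  (normalisation over topics)

where `m(w)` is the tweet of word occurrence `w`, and from it: topic counts
`N` and `N_norm = N/O`, Shannon entropy in nats, pairwise Jensen–Shannon
distances between rings (bounded by `sqrt(ln 2) ≈ 0.83`), a two-class Jenks
natural-breaks split into primary (`U_r`) and non-primary (`L_r`) topics,
and the cross-ring *pulling power* statistics (coverage `K_TOP`, strengths
`S_TOP`, `S_BOTTOM`, joint strengths over `U_rx ∩ U_ry` and `U_rx ∩ L_ry`,
and sigma contrasts with paired t-tests).  A word-shuffling null model that
exactly preserves ring sizes and per-ring occurrence totals separates what
is due to the layered structure from what is due to which words sit where.

It is intended for computational social scientists and quantitative
linguists who want a tested, scriptable implementation of the layered
vocabulary model — plus a synthetic-corpus generator with full ground truth,
so every stage is testable without any platform data.

## Worked example

Generate one synthetic ego at the default study conditions, build its ego
network and inspect its rings:

```python
from egowords import preprocess
from egowords.ego_structure import ego_network_from_stream
from egowords.semantic_profile import ego_profiles, ring_descriptors, distance_matrix
from egowords.synthetic_data import SyntheticConfig, generate_ego

config = SyntheticConfig()
timeline, assignments, truth = generate_ego(config, seed=42, ego_id="egoA")
stream = preprocess.process_timeline(
    preprocess.window_timeline(timeline, config.T), preprocess.load_stopwords()
)
net = ego_network_from_stream(stream, T=config.T)
print("tau =", net.tau)
print("layer sizes =", [int(s) for s in net.layer_sizes()])
print("scaling ratios =", [round(float(r), 2) for r in net.scaling_ratios()])

topics = config.topic_ids()
profs = ego_profiles(net, stream, assignments, topics)
print(ring_descriptors(net, stream, assignments, topics).round(4).to_string(index=False))
mat = distance_matrix(profs)
print("mean JS distance from ring 1:", round(float(mat.loc[1].drop(1).mean()), 3))
print("mean JS distance from ring 6:", round(float(mat.loc[6].drop(6).mean()), 3))
```

prints

```
tau = 6
layer sizes = [3, 18, 48, 106, 228, 468]
scaling ratios = [6.0, 2.67, 2.21, 2.15, 2.05]
ego_id  ring  N  N_norm      H    O
  egoA     1 50  0.0098 1.6810 5121
  egoA     2 11  0.0012 2.2773 9552
  egoA     3 14  0.0019 2.4334 7188
  egoA     4 18  0.0034 2.7044 5328
  egoA     5 18  0.0042 2.6821 4294
  egoA     6 19  0.0064 2.7233 2947
mean JS distance from ring 1: 0.538
mean JS distance from ring 6: 0.317
```

Reading this: the clustering found six frequency layers; layer sizes roughly
double outwards while the innermost layer is several times smaller than the
next (scaling ratio 6.0 then ~2).  Ring 1 — three lemmas, 5121 occurrences —
touches all 50 topics (highest `N_norm`), has the lowest entropy (its mass
concentrates on the ego's fingerprint topics), and is semantically the most
distant ring (mean JS 0.538 vs 0.317 for ring 6): the innermost ring acts as
the semantic fingerprint of the whole network.

The same pipeline runs from the shell:

```bash
egowords synth --out corpus/ --n-egos 20 --seed 1
egowords all --timelines corpus/timelines.jsonl \
             --assignments corpus/assignments.tsv --out results/
```

writing TSV tables (`ego_networks`, `structure_summary`, `profiles`,
`ring_descriptors`, `js_matrix`, `primary_splits`, `pulling_power`,
`null_descriptors`) plus a manifest of row counts and the config hash.

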