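# meshsom

Self-organizing maps of annotated literature corpora: batch training on
sparse binary MeSH-style vectors, topographic-error model selection,
projection of document sets onto the trained grid, k-means/elbow cluster
interpretation, and edition-level citation statistics.

## The problem

Controlled-vocabulary indexes such as Medline describe each article by a
small set of subject headings (on average ~9 MeSH out of ~29,917). Encoding
every article as a binary vector **x**ᵢ ∈ {0,1}ᴰ and fitting a Kohonen
self-organizing map produces a two-dimensional knowledge map of the
literature: each grid node *j* carries a weight vector **w**ⱼ ∈ [0,1]ᴰ, and
after training, nearby nodes represent similar subject-heading profiles.
Projecting an *independently chosen* document set — for instance the
Medline-indexed references of successive editions of a standard psychiatry
textbook — onto the map and clustering the projected positions tests whether
the map organizes expert-curated knowledge coherently: stable, interpretable
clusters across editions validate the map's semantics.

`meshsom` implements this pipeline end to end at configurable scale,
together with a synthetic-data generator that plants known topic structure
and citation-persistence rates so every stage can be validated against
ground truth without any download.

## Method

**Batch SOM on sparse binary data.** Each epoch assigns every article its
best matching unit (BMU) b₁(i) = argminⱼ ‖xᵢ − wⱼ‖² against the frozen
pre-epoch codebook, using the expansion ‖xᵢ−wⱼ‖² = ‖xᵢ‖² + ‖wⱼ‖² − 2 xᵢ·wⱼ
so each article is touched only at its nonzero columns. Weights are then
replaced by neighborhood-weighted means,

    wⱼ ← Σᵢ h(b₁(i), j) xᵢ / Σᵢ h(b₁(i), j),   h(b, j) = exp(−d²(b,j) / 2σ²(e)),

with Euclidean grid distance d and a shrinking neighborhood width
σ(e) = σ₀ / 1.7ᵉ (full scale: σ₀ = 175 on a 350×350 grid, 20 epochs). The
**topographic error** — the fraction of articles whose first and second BMUs
are not grid-adjacent (8-neighborhood) — is evaluated after every epoch, and
the codebook with the lowest error is kept. Nodes are classified as
domain (e.g. psychiatric) when their mean weight over the domain subtree's
columns exceeds their mean weight elsewhere.

**Interpretation layer.** A document set is projected to BMU grid positions;
k-means (k-means++, best of restarts) clusters the positions; the cluster
count is chosen at the elbow of the within-cluster sum-of-squares curve
(maximum perpendicular distance to the chord); each cluster is described by
its ten most frequent vocabulary terms and the ten member articles carrying
most of them, plus a 95% bivariate-normal ellipse (scale² = χ²₀.₉₅(2) ≈ 5.99).

**Edition statistics.** Citations per chapter, the percentage of an
edition's indexed citations already present in its predecessor, and
cross-edition means, with half-up rounding to the conventional printed
precision. The packaged table `meshsom/data/textbook_editions.tsv` carries
the organizational features of the ten editions (1967–2017) of a
comprehensive psychiatry textbook.

## Worked example

```sh
python examples/02_project_and_cluster.py
```

```
projected 2000 articles; 125 of 400 nodes occupied
elbow-selected k = 4 (WSS 207947 at k=1 down to 2233 at k=12)
cluster 0: top terms [T011, T015, T012], 95% ellipse center (18.6, 2.1)
cluster 1: top terms [T005, T004, T009], 95% ellipse center (5.8, 18.9)
cluster 2: top terms [T034, T031, T039], 95% ellipse center (1.3, 0.2)
cluster 3: top terms [T027, T023, T020], 95% ellipse center (7.6, 9.9)

adjusted Rand index vs planted topics: 0.959
```

Four topics were planted into 2,000 synthetic articles; after training a
20×20 map, the elbow criterion recovers k = 4, each cluster's defining terms
are its planted signature, and the clustering agrees with the hidden topic
labels at ARI 0.96 (1.0 would be perfect recovery).

The other examples train a map and report its topographic-error history
(`01`), match free-text references against a local bibliographic record set
(`03`), and reproduce the edition-level citation statistics (`04`). The
same capabilities are exposed as a CLI:

```sh
meshsom simulate --out-dir sim --seed 1
meshsom train --vocabulary sim/vocabulary.tsv --corpus sim/corpus.jsonl \
    --out-dir run --grid 20 20 --min-term-count 0 --init pca_sample
meshsom cluster --codebook run/codebook.h5 --vocabulary sim/vocabulary.tsv \
    --corpus sim/corpus.jsonl --out-dir clusters
meshsom stats --out-dir stats
```

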