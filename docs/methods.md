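# Methods

## Model and assumptions

`meshsom` fits a square-grid Kohonen self-organizing map to corpora of
articles encoded as sparse binary vectors over a controlled vocabulary. The
batch variant is used throughout: all best-matching-unit (BMU) assignments
in an epoch are made against the frozen pre-epoch codebook, and weights are
replaced at epoch end by Gaussian-neighborhood-weighted input means. Because
the inputs are binary, the per-node input sums are exact integers in
float64, which makes an epoch *bitwise* invariant to article order — a
property the test suite asserts rather than approximates.

The working assumptions are those of the underlying encoding: annotations
are treated as exchangeable binary features (no heading is down-weighted, no
hierarchy information enters the distance), and squared Euclidean distance —
equivalent to Hamming distance on binary data up to the node weights — is
the dissimilarity everywhere. Whether an inner-product dissimilarity would
organize such corpora differently is untested here; Euclidean was chosen
because the batch update (a convex combination of inputs) is its natural
companion, and it keeps every trained weight inside [0,1].

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| R × C | grid size (nodes) | 350×350 full scale; ≤30×30 in tests | full scale matches the mapped-literature use case; tests stay small |
| E | training epochs | 20 | fixed by the schedule below |
| σ₀ | initial neighborhood width (grid units) | 175 full scale; 9 on a 20×20 grid | half the grid side at full scale; just under half at toy scale |
| decay | per-epoch width divisor | 1.7 | σ(e) = σ₀/1.7ᵉ, e = 1..E; σ falls below one grid unit at epoch 10 for the full-scale schedule |
| kernel | neighborhood function | gaussian (bubble available) | standard batch-SOM form implied by a σ(e) schedule |
| adjacency | topographic-error neighborhood | 8 (Chebyshev 1); 4 available | diagonal neighbors are topological neighbors on a square grid |
| min_term_count | rare-term exclusion | 100 full scale; 0 in toy runs | headings annotating fewer articles carry no stable geometry |
| ε | dead-node threshold on the kernel mass Zⱼ | 1e−12 | avoids 0/0; the node keeps its weights for that epoch |
| K_max | elbow scan bound | 12 | about double the cluster count expected in the textbook use case |
| restarts | k-means restarts | 10 | WSS curves must be near-optimal per k for the elbow to be meaningful |
| title / journal thresholds | fuzzy match acceptance | 0.90 / 0.80 | emulate a human verifier's tolerance to punctuation and abbreviation drift; set both to 1.0 for exact matching |

Epoch indexing starts at 1, so the first epoch already trains below σ₀; an
epoch-0 convention would merely prepend one ultra-smooth epoch.

## Codebook initialization and selection

Three initializations are provided:

* **sample** (default): every node is a uniformly sampled (seeded) article
  vector plus jitter of magnitude 1e−3. Data-vector initialization is
  essential on binary corpora — uniform-random weights sit far from all
  inputs and make early BMU competition pathological.
* **pca**: the deterministic linear initialization, mapping grid coordinates
  onto the top two principal components over ±2 SD.
* **pca_sample**: 0.7·pca + 0.3·sampled articles, clipped to [0,1].

The trained codebook is the one with the lowest topographic error across
all epochs (and, when `restarts > 1`, across independently initialized
training runs; restart r uses seed `rng_seed + 100003·r`). Ties go to the
earliest restart and epoch. BMU ties go to the lowest linear node index,
and the second BMU excludes only the first (not nodes tied with it).

The blended initialization plus restart selection exists because of a
failure mode observed while validating on planted-topic corpora: with a few
discrete, near-orthogonal topics on a small grid, pure article sampling
frequently produces *topological folds* (a topic split across disjoint grid
islands), while the error-minimizing epoch is almost always an early,
smooth one whose layout is essentially the initialization's layout. Folds
inflate exactly the quantity the selection rule minimizes — the topographic
error — so selecting over a handful of restarts removes them; the principal
plane supplies global order, and the sampled-article component keeps node
weights dispersed onto realistic vectors. A second, subtler effect also
surfaced: the class means of G exchangeable topics form a regular simplex
whose top-2 principal plane is degenerate, so a pure-PCA layout is randomly
oriented between "square" and "triangle plus center" arrangements; the
latter can make a 3-cluster partition the genuine elbow of the projected
positions. The blended initialization with restart selection resolves this
in practice (validated over 32 generator seeds: adjusted Rand index ≥ 0.8
and elbow = 4 in 31/32, with the single failure an elbow of 3 at ARI 0.94).

## Interpretive layer

k-means runs on raw (row, col) BMU coordinates with duplicates retained —
every article counts, so dense nodes weigh more. The elbow is the k whose
WSS point lies farthest (perpendicular) from the chord joining k = 1 and
k = K_max; constant or straight-line curves return k = 1 with a warning.
Cluster characterization ranks terms by member frequency (ties
alphabetically by label), scores each member by how many of the top-10
terms it carries, and ranks exemplars by that score (ties by input order);
clusters smaller than ten report all members unpadded. The 95% normal
ellipse uses the sample mean and covariance with scale √χ²₀.₉₅(2);
collinear clusters raise rather than emit a degenerate ellipse. Cross-
edition cluster matching is greedy by ascending centroid distance — the
comparison it supports is visual/descriptive, so a transparent rule beats
an optimal-assignment one; Jaccard overlap is computed on occupied node
sets.

## Reference matching

Free-text references are parsed by a sentence-segment heuristic (author
block / title / journal; trailing numeric segments discarded), normalized
(lower-case, punctuation stripped, whitespace collapsed), and matched
against records sharing the first author's surname. Acceptance requires the
normalized Levenshtein ratio (via edlib) to clear both the title and
journal thresholds, uniquely; two passing candidates are rejected as
ambiguous. Raising a threshold therefore cannot create matches *except*
through that ambiguity rule (a tie can resolve to unique); the monotonicity
property holds whenever no two records are near-duplicates, which is how
the property is tested. Matching is order-independent by construction:
candidates are compared as a scored set with deterministic tie-breaks.

## Edition statistics

Citations per chapter = citations / chapters, rounded half-up to one
decimal. Persistence is directional: the share of the *current* edition's
indexed citations already present in the *previous* edition, rounded
half-up to a whole percent — the direction under which a second edition can
be measured against a first. Aggregates are arithmetic means over editions
after the first (a first edition has no predecessor, so its printed
chapter-turnover value is excluded along with its undefined persistence).
The packaged ten-edition table stores the printed values; where the source
text and table disagree on one persistence entry (55% vs 56% for the 3rd
edition), the table value is stored.

## Synthetic data: what it emulates, and what it does not

The generator produces (a) a vocabulary with dot-numbered tree paths and a
designated domain subtree; (b) planted-topic corpora — per article a
uniform topic, an annotation count drawn Poisson(9) truncated at ≥1, and
each annotation from the topic's signature with probability 0.9 (default)
else uniform background, drawn until the target number of *distinct* terms
is reached; (c) edition citation lists in which each id persists to the
next edition with a planted probability, with fresh ids drawn outside the
previous edition so the measured persistence is exactly binomial (a
consequence: at rate 0 consecutive editions are exactly disjoint).

This emulates the sparsity, topical clustering, and persistence structure
of an annotated literature; it does not emulate correlated topic overlap,
heading drift over decades, citation-network structure, or the long-tailed
heading frequencies of a real thesaurus. Passing recovery tests therefore
demonstrates that the pipeline is correct and sensitive under clean planted
structure — not that a real corpus of comparable size would organize as
cleanly.

## Problem sizes

Tests and the acceptance study run at deliberately small scale: grids ≤
30×30, corpora ≤ 2,000 articles, vocabularies ≤ 300 terms for training runs
(29,917 only for the encoding check), with the topic-recovery study at
4 topics / 2,000 articles / 20×20 / 20 epochs × 5 restarts and the
persistence study at 10 editions × 4,000 citations from a 50,000-article
pool. The implementation supports full-scale geometry (350×350), but the
neighborhood matrix is built densely per epoch (M×M), so paper-scale
training would want a separable-kernel refactor first — a known limitation.

## Other numerical choices

* Weight updates are convex combinations of binary inputs, so all trained
  weights stay in [0,1]; the initializations clip to the same box.
* Codebooks persist to HDF5 (float64, bitwise round-trip) with geometry,
  schedule, error history, and a vocabulary digest; loading under a
  different vocabulary warns on digest mismatch.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the schedule/config; training with a fixed seed is bit-reproducible, and
  every CLI run writes a provenance JSON (config, seeds, input digests,
  version).
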