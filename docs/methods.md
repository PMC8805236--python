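# Methods

## Model

The package treats a corpus of MEDLINE-style citations as points in the
"feature space" spanned by a term similarity network. Three similarity
measures share one evaluation harness:

* **MCRWR** — random walk with restart on the MeSH-concept network;
* **MRWR** — the same walk on the MeSH-only network (ablation of the
  concept expansion);
* **PMRA** — the two-Poisson shared-stem baseline.

The core assumption of the walk-based measures is that two documents are
similar when their index terms are close in the term network — either
directly (high tree-number similarity, shared concepts) or through bridging
terms the walk can traverse. The network is undirected and weighted; all
weights lie in (0, 1].

### Information-content similarity

Informativeness of a tree number is the negative log of its subtree's share
of the corpus frequency mass. Two choices the formula itself leaves open:

* **Log base** — natural log. The base only rescales distances, and the
  decay scale ε absorbs the units; ε = 3 is kept as the standard default.
* **Counting** — each occurrence of a major MeSH term in a document
  increments the count of *every* tree number of that term; N is the total
  tree-number occurrence count. This keeps every subtree-mass ratio ≤ 1,
  which a term-token denominator would not guarantee for multi-number terms.
* **Smoothing** — vocabulary tree numbers unobserved in the corpus receive
  a pseudo-count of 1 (and N grows accordingly), so `I(v)` is always finite
  and subtree masses are always positive.
* **Disjoint categories** — the closest common ancestor of codes whose
  first segments differ is a virtual root with `I = 0`, consistent with the
  root of the classification forest being uninformative. The cca of a node
  with its own ancestor is that ancestor, making the distance along an
  ancestry chain the difference of informativeness.

### Network construction

All-pairs average-maximum-match similarity over the MeSH terms observed in
the corpus, with an edge-inclusion threshold `min_sim` (default 0.1).
The threshold is a genuine free parameter: exponential-form similarities
are strictly positive, so some cutoff is required to keep the graph from
being complete; published term networks of this kind are far sparser than
complete, but no explicit rule accompanies them, so the cutoff is exposed
in the configuration rather than hard-coded.

Concept expansion adds one global node per CUI (node kinds keep concepts
distinct from identically named MeSH terms), linked to the MeSH terms of
every document that retained the concept; duplicate links keep the maximum
weight; zero-weight links (the corpus-wide TF-IDF minimum maps to 0 under
min-max normalisation) are skipped. Node accounting is exactly
`|V_expanded| = |V| + L` with L the number of linked distinct concepts.

### Random walk with restart

`p ← (1−α)W p + αq`, `p⁰ = q`, stopping when the L1 step difference is
≤ 1e−10 (iteration cap 10,000). Choices:

* **Transfer matrix** — column normalisation of the weighted adjacency
  (each column is the node's outgoing distribution). A weighted adjacency
  matrix is not itself stochastic, so a normalisation must be chosen; the
  symmetric form `D^{-1/2} A D^{-1/2}` is available via `RWRConfig(norm=
  "laplacian")` for experiments, but the stochastic column form is the
  default because it conserves probability mass (tested to 1e−9 per
  iteration). Isolated nodes get self-loop columns.
* **Restart vector** — uniform `1/|seeds|` over the document's seed nodes
  rather than raw indicator 1s. Downstream cosine similarity is invariant
  to uniform scaling of `q`, so this choice only fixes the "Σp = 1"
  invariant; it does not change any similarity.
* α = 0.6; smaller α diffuses further from the seeds. A dense linear-solve
  fixed point (`rwr_closed_form`) serves as the verification oracle; the
  iterate agrees with it to 1e−8 (L∞) on random graphs up to 500 nodes.

### Annotation

Preprocessing lower-cases and deletes punctuation and digits before
whitespace tokenisation (so "p53" becomes "p"); no stopword removal. PMRA
uses classic Porter stems with title occurrences weighted ×2 and document
length l = Σ weighted frequencies — the weighting keeps k and l on one
scale; idf = ln(D/df) without smoothing. The concept annotator is a greedy
longest-match, non-overlapping dictionary matcher over the preprocessed
token stream — a deliberate, deterministic simplification of
MetaMap-style candidate scoring (no word-sense disambiguation, no match
threshold). Top-5 selection breaks ties by higher TF then lexicographically
smaller CUI; min-max normalisation of retained TF-IDF is corpus-global,
with the degenerate all-equal case mapping to 1.

### PMRA

Restricted to title+abstract stems (MeSH terms are not part of the shared
term sum). Pairwise scores are computed as the Gram matrix of the
per-document weight matrix, which equals the shared-stem double loop
because absent stems carry weight 0; the double loop is kept as the test
oracle. Scores are min-max normalised over off-diagonal pairs globally
(not per query); the diagonal is set to 1.

### Evaluation

Pairs are pooled across topics; a pair is relevant iff the documents share
at least one topic. The ROC sweep uses every distinct similarity value as a
threshold and integrates by trapezoid, which coincides with the rank-based
(Mann–Whitney) AUC to 1e−9 — the identity is asserted in tests against an
independent implementation. P5 ranks *all* other judged corpus documents
per query (ties broken by pmid), keeps the top five, divides by five even
when the topic has fewer than five other members (so small topics cannot
exceed 2/5), averages per topic and then macro-averages over topics.
Per-topic precision counts pairs with at least one member in the topic and
is reported as missing, not zero, where nothing is predicted similar.
Community detection delegates to igraph's Infomap (map-equation) with a
deterministic seeded fallback (label propagation); community/topic verdicts
are set comparisons restricted to clustered documents.

## Synthetic data

The generator emulates a topic-annotated MEDLINE subset: a forest of
complete b-ary dotted hierarchies (default branching 3, depth 3; one root
category per topic; root segments are categories, not terms), one term per
node, 10% of terms carrying a second tree number in another category. Each
topic anchors to a depth-1 "home" subtree; documents draw 3–5 MeSH terms
from their home with 10% leakage, and five concepts per document from an
8-concept topic pool (rate 0.6) or 30 shared filler concepts. Titles
(4–8 tokens) and abstracts (50–150 tokens, a fixed filler word list with
~15% concept-phrase insertions) give the stem baseline realistic shared-
token noise. 10% of documents belong to a second topic. `topic_separation`
∈ [0,1] sets how many distinct root categories host home subtrees; the
vocabulary itself is independent of the dial, so only term placement
changes. All sampling is integer-based from one `random.Random(seed)`,
making bundles byte-identical across platforms.

What passing on this generator shows — and does not show: the synthetic
corpus has clean topic structure, uniform record quality, a closed concept
lexicon and no annotation noise. Results demonstrate correctness of the
machinery and the qualitative ordering of the methods under separable
topics; they do not predict absolute AUC/P5 on real MEDLINE corpora, where
vocabulary size, annotation depth and topic overlap differ by orders of
magnitude.

## Problem sizes

The default test and benchmark configurations use 5 topics × 20 documents
(benchmark), 3 topics × 6–8 documents (unit fixtures), random walk oracle
graphs up to 500 nodes, and published-size graphs (2438 and 7302 nodes)
only for degree arithmetic — sizes chosen so the whole suite runs in well
under a minute while still exercising every code path at meaningful scale.

## Known limitations

* The dictionary concept matcher has no analogue of MetaMap's match-score
  threshold; rare surface strings either match exactly or not at all.
* Real MeSH qualifier hierarchies, supplementary concepts and entry terms
  are out of scope; the vocabulary is a flat term → tree-number table.
* Clustering coefficients of large published networks are not reproduction
  targets: they depend on an edge-inclusion rule that is not identified,
  whereas degree arithmetic is rule-independent.
* The Infomap optimiser is treated as a black box behind a pluggable
  contract; its internal stochasticity is controlled only through seeding.
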