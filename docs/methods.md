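# Methods

## Pipeline overview

`cannanet` converts a corpus of full-text articles into a typed co-occurrence
network in six stages: ingest (XML/JSONL parsing, language filter), tag
(dictionary NER), count (paragraph-level occurrence and co-occurrence
accumulation), test (log-likelihood-ratio association scoring), build
(multipartite graph materialization with provenance), and query (subgraph
extraction, degree filtering, heatmaps).  A skip-gram embedding stage expands
the therapeutic-property lexicon before tagging; a synthetic-corpus generator
supplies ground-truth data for validation.

## Units and granularity

The unit of co-occurrence is the body paragraph.  All probabilities are
paragraph-presence probabilities: `c(e)` counts paragraphs containing entity
`e` at least once, never total mentions, so the 2×2 contingency table is a
partition of the `N` scanned paragraphs.  Mention multiplicity enters only
through the edge weight: per co-occurring paragraph, the product of the two
entities' mention counts, summed over paragraphs.  Abstracts are excluded
from co-occurrence by default (`include_abstract` flips this): the mined
signal is defined on full-text body paragraphs, and mixing in abstracts
changes `N` in a way that is hard to reason about across journals.

Two relation types are mined — gene–chemical and chemical–property — so
chemicals are the bridging partition.  Same-type pairs and gene–property
pairs are never counted.  Strain–chemical edges are curated input (a
two-column TSV), added with weight 1 and no test attributes.

## Language filtering

Non-English documents are removed by a stopword-ratio heuristic: the document
passes if at least `stopword_ratio_min` (default 0.15) of the lowercased
alphabetic tokens in title + abstract appear in a built-in English
function-word list.  The list deliberately omits forms shared with other
European languages ("die", "das", "von", "auf"), which is what makes the
ratio discriminative.  This is deterministic and dependency-free; it is a
coarse filter and will misjudge very short or heavily technical titles, which
is acceptable because a few stray documents only add noise edges with low
weights.

## Entity tagging

The default tagger is a dictionary matcher: paragraph text is normalized
(lowercase; hyphens/underscores/whitespace runs collapsed to single spaces;
token-edge punctuation stripped) and scanned left to right with greedy
longest match over token runs.  A token consumed by one match cannot
contribute to another, which resolves nested names — "cannabidiolic acid
synthase" matches the gene surface, not the embedded chemical.  Equal-length
ties across types break by the fixed priority gene > chemical > property >
strain, on the argument that gene surfaces are the rarest and most specific.
No stemming or lemmatization is applied; inflected property forms belong in
the lexicon as additional surfaces.

External model taggers (e.g. a bioNER pipeline) plug in through
`external_tagger_adapter`, which normalizes their spans, resolves canonicals
through the lexicon (unknown surfaces become their own canonical), and
deduplicates repeated spans by character position.  Dictionary matcher and
adapter emit identical `Mention` records, so downstream stages are
tagger-agnostic.

## Association test

The score is the Dunning log-likelihood ratio for collocations, computed
from the 2×2 table with binomial log-likelihoods under the convention
0·ln 0 = 0, and compared with the χ²(1) quantile at level α (default 0.05,
`scipy.stats.chi2`).  Values below 1e-12 are snapped to exactly 0 so that
independence-structured tables (proportional rows) score zero despite
floating-point rounding.  The statistic is symmetric in the two entities.

No multiple-testing correction is applied by default; a Bonferroni option
over the scored pairs exists behind a flag.  The default `min_pair_count` is
1, so single-paragraph co-occurrences are scored and retained — the network
is deliberately permissive, storing `significant` and `direction` as edge
attributes rather than pruning; a `significant_only` build mode provides the
strict alternative.  Direction uses the conditional ratios r_a = k₁₁/c(a)
and r_g = k₁₁/c(g) against τ (default 0.8, i.e. "at least 80% of the
paragraphs containing *a* also contain *g*").  τ and α are exposed in
`PipelineConfig`; both defaults are conventional rather than derived.

## Embedding expansion

Skip-gram with negative sampling, implemented in numpy: unigram^0.75 noise
distribution, 5 negatives per context word, dynamic window, linear
learning-rate decay from 0.025 to 1e-4.  Training is single-threaded with
one seeded generator, so a (corpus, seed) pair reproduces vectors bit-for-bit
— multi-worker word2vec trainers do not guarantee this, and reproducibility
was weighted over speed here.  Before training, adjacent token pairs
occurring at least `bigram_min_count` times (default 25) are merged into
single `a_b` tokens so multi-word properties can embed.  Defaults d=100,
window=5, min_count=5, epochs=5, cosine threshold 0.7, top_k=10; none of
these is canonical and all are config-exposed.  Expansion emits a TSV review
report and a merged candidate list; accepted terms are added to the property
lexicon by a human, never automatically.

## Graph semantics

The graph is undirected (`networkx.Graph`); node identity is
(canonical, etype), so a string appearing as both gene and chemical yields
two nodes.  Edges carry weight, LLR, significance, direction class, and
provenance: the set of (doc_id, paragraph index) keys whose cardinality
equals the pair's paragraph co-occurrence count, plus a citation snapshot
per source document.  Exports: GraphML (provenance as a count), edge-list
TSV, and a full-fidelity JSON dump that round-trips through
`read_json_graph`.  The summary reports node/edge counts, per-type node
counts, and the average degree 2|E|/|V| (also as a rounded integer, the form
used in reporting).

## Subgraph querying

Queries resolve canonical names to all matching typed nodes and take the
one-hop induced neighborhood by default (`hops` option for more).  Degree
filtering is single-pass: nodes below the threshold (by the *input*
subgraph's local degrees) are removed, dangling edges drop, and degrees are
recomputed — so surviving nodes' local degrees shrink between successive
filter calls, which is the behavior wanted for progressive manual filtering
at increasing thresholds.  An `iterate` flag gives the k-core-like
fixed-point variant instead.  Queried anchors are protected from removal by
default so a query can never delete its own subject.  Heatmaps are
edge-weight matrices between two node types (rows/columns sorted by name,
absent edges 0); a `values=degree` variant fills cells with the summed local
degrees of connected endpoints instead.

## Synthetic corpus generator

The generator emulates the corpus features the pipeline depends on — planted
entity mentions with controlled marginal rates, controlled pairwise
dependence, and known mention-count distributions — and none it does not
(no grammar, no discourse structure, no ambiguous surface forms unless the
adversarial mode is on).  Per paragraph, each entity is included by a
Bernoulli draw at its base rate; a dependent pair is drawn from the 2×2
joint distribution with joint probability `boost·p1·p2` (capped at
min(p1, p2)) and unchanged marginals.  Included entities receive mention
counts from a shifted geometric (default q=0.5, support {1, 2, ...}) or a
fixed count for exact-weight tests.  Mentions are embedded among filler
tokens (`fillerNNNN`) disjoint from every lexicon surface, so matcher
precision is exactly 1 by construction; the adversarial mode adds near-miss
strings (surface tokens with appended characters, proper prefixes of
multi-word surfaces) that must not match, exercising the longest-match
boundary.  Default scale is 10 documents × 20 paragraphs; validation suites
use 2,000-paragraph corpora for calibration and 5,000-paragraph corpora for
recovery, sizes at which the χ²(1) asymptotics of the test are comfortably
valid at the default 0.05–0.1 base rates.

Passing tests on synthetic data demonstrate the counting, testing and graph
machinery exactly; they do not demonstrate NER quality on real prose, which
is bounded by the lexicon (or external tagger) supplied by the user.

## Numerical and degenerate-input choices

- LLR requires both row marginals positive; zero-marginal tables raise
  rather than returning 0, since the test is undefined there.
- Contingency cells are validated non-negative and summing to N ≥ 1.
- Cosine similarity rejects zero vectors rather than defining them as 0.
- Empty corpora, empty lexicons, and empty graphs are legal inputs with
  empty outputs; duplicate document ids and conflicting lexicon surfaces are
  validation errors that name the offender.
- All randomness (generator, embeddings, layouts) flows through explicit
  seeds; the pipeline writes a manifest (config, input checksums, versions)
  for byte-reproducible reruns.

## Known limitations

- Co-occurrence is not causation: edges record paragraph-level association,
  and the direction class is a containment heuristic, not extracted
  semantics (no "precursor"/"product" labels).
- Dictionary NER misses surfaces absent from the lexicon; recall on real
  corpora depends entirely on lexicon coverage.
- The permissive default keeps weight-1, non-significant edges; strict mode
  changes the network's size materially.
- The embedding trainer is adequate for the corpus sizes a desk analysis
  handles; for very large corpora an external trainer behind the same model
  interface would be preferable.
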