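# cannanet

Mine gene–chemical–therapeutic-property relationship networks from full-text
biomedical corpora.

Researchers studying a medicinal plant such as *Cannabis sativa* face a
scattered literature: which genes make which chemical constituents, and which
therapeutic properties those chemicals carry, is spread across tens of
thousands of articles.  `cannanet` turns a corpus of full-text documents into
an undirected, weighted, multipartite co-occurrence network — genes linked to
chemicals, chemicals linked to therapeutic properties, plus manually curated
strain→chemical edges — with every edge backed by the exact paragraphs that
support it.  It is aimed at plant breeders, natural-product chemists and
pharmacology researchers who want the complete property and gene set for any
chemical, with the source text one lookup away.

## The model

Processing is paragraph-by-paragraph.  For entities *a* and *g* with
paragraph-presence probabilities *p(a)*, *p(g)* and joint probability
*p(a, g)* over the *N* corpus paragraphs, an association is asserted when the
pair co-occurs more often than independence predicts.  Candidate pairs are
scored with the Dunning log-likelihood ratio over the 2×2 paragraph table
(k₁₁ both, k₁₂ *a* only, k₂₁ *g* only, k₂₂ neither):

```
LLR = 2·[ ℓ(k₁₁, n₁, p₁) + ℓ(k₁₂, n₂, p₂) − ℓ(k₁₁, n₁, p) − ℓ(k₁₂, n₂, p) ]
ℓ(x, n, q) = x·ln q + (n−x)·ln(1−q),   n₁ = k₁₁+k₂₁,  n₂ = k₁₂+k₂₂
```

which is asymptotically χ²(1) under independence; significance at level α
uses the χ²(1) critical value.  The relation "*p(a) ≈ p(a, g)*" is
operationalized by conditional ratios r_a = k₁₁/c(a), r_g = k₁₁/c(g) against
a threshold τ: both high ⇒ bidirectional, one high ⇒ unidirectional, carried
as edge attributes on the undirected graph.  Edge weight is the sum over
co-occurring paragraphs of the product of the two entities' in-paragraph
mention counts.  Only gene–chemical and chemical–property pairs form mined
edges; strain–chemical edges come from a curated table.

Entity tagging is dictionary-based (greedy longest match over normalized
tokens), with an adapter seam for external bioNER models.  The
therapeutic-property lexicon can be expanded by training skip-gram word
embeddings on the corpus and collecting cosine-similarity neighbors of a
manually curated seed list; the expansion output is a review file, not an
automatic lexicon update.

## Worked example

Generate a synthetic corpus with one planted gene–chemical dependence
(`cbda`–`cbdas`, joint occurrence boosted 8× over independence), build the
network, and query it:

```
$ cannanet simulate --spec spec.json --out corpus.jsonl --truth truth.json
wrote 40 documents / 2000 paragraphs to corpus.jsonl

$ cannanet build --corpus corpus.jsonl --lexicon lexicon.tsv \
      --strain-table strains.tsv --out-dir out
{
 "average_degree": 2.6666666666666665,
 "average_degree_rounded": 3,
 "edge_count": 8,
 "node_count": 6,
 "node_count_by_type": {
  "chemical": 2, "gene": 1, "property": 2, "strain": 1
 }
}
```

The association report (`out/associations.tsv`) shows the planted pair
standing far above the χ²(1) critical value while an independent pair does
not:

```
entity_a  etype_a   entity_g  etype_g   relation       llr        significant  direction   weight
cbda      chemical  cbdas     gene      gene_chemical  371.946    1            undirected  373
cbdas     gene      cbga      chemical  gene_chemical  0.0788981  0            undirected  32
```

`llr = 371.9` means the co-occurrence of `cbda` and `cbdas` is overwhelmingly
unlikely under independence (critical value 3.84 at α = 0.05); `weight = 373`
is the summed product of their per-paragraph mention counts.  A subgraph
query with an edge-weight heatmap between node types:

```
$ cannanet query --graph out/graph.json --nodes cbda,cbdas \
      --heatmap chemical property --out sub2
subgraph: 6 nodes, 8 edges
$ cat sub2.heatmap.csv
,analgesic,antiviral
cbda,64,93
cbga,99,32
```

Each cell is the total co-mention weight between a chemical (row) and a
property (column); zero cells are either therapeutic dead ends or unexplored
territory.

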