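# Methods

This note documents the models implemented in `datamed-rank`, the defaults
and the reasoning behind the open design choices, and what the synthetic
test conditions do and do not demonstrate.

## Text normalization

Corpus text (title + flattened metadata) and queries run through one
pipeline, in this order: (1) Greek letters are replaced by their literal
names (both cases, final sigma included); (2) lowercasing and tokenization
at non-alphanumeric boundaries; (3) stopword removal — a standard English
list for all text, plus a *query stopword* list of search-intent words
(`find`, `search`, `data`, `datasets`, `databases`, `related`, `types`,
`mention`, `regarding`, `across`, `all`) applied only in query mode, since
words like "data" are content-free in a dataset-search request yet absent
from general stopword lists; (4) Porter stemming (the original algorithm,
implemented in-package); (5) removal of any remaining non-alphanumeric
characters; (6) truncation to 20 characters; (7) purely numeric tokens
collapse to the literal `_number_`. The numeric substitution runs last so
its underscores survive the non-alphanumeric strip. Both stopword lists
ship as editable resource files.

Normalization is not exactly idempotent: a stem can itself stem further
("agree" → "agre") or collide with a stopword string ("ase" → "as"), so
re-running the pipeline on its own output may drop or shorten rare tokens.
It never invents tokens; the property tests pin this down.

## Metadata flattening

Only string leaves of the metadata JSON (and string elements of arrays)
enter the indexed text, concatenated depth-first in sorted-key order; keys
are excluded by default (the values, not the attribute names, carry
content) with an `include_keys` switch. Records with unparseable JSON keep
the raw text between the metadata tags. Title and metadata are pooled into
one field; no per-field weighting is applied.

## Key relevance

A query term is **key-relevant** iff its collection document frequency is
at or below the median document frequency of the query's terms (even-count
median = mean of the middle pair); terms absent from the index are
key-relevant by convention (df 0 is always ≤ the median). Document
frequency means "number of documents containing the term"; a config
switch (`df_mode="occurrences"`) substitutes total occurrence counts for
sensitivity analysis.

## RTRL scoring

Each query term t present in document d contributes
`w(t,d) = expansion_weight(t) · (w_d + w_q)` with

* `w_d = w_d' = 1` when `f(t,d) = 1`, `w_d'' = 2·w_d'` when the term
  repeats (a two-level step function — beyond "repeated", frequency is
  deliberately ignored for robustness on short queries);
* `w_q = w_q' = 1` for relevant terms and `w_q'' = c(2L−2)` for
  key-relevant terms, `L` = number of original query terms, gain `c ≥ 1`
  (default 1).

`c(2L−2)` is the minimal integer solution of the worst-case dominance
inequality `k(w_d' + w_q'') ≥ (k−1)(w_d'' + w_q'') + (L−k)(w_d'' + w_q')`
under the defaults and the assumption `k ≈ L/2`; equality holds at
`k = L/2` for even L (for odd L the tight case is `k = ⌈L/2⌉`, margin 1).
Single-term queries are degenerate (`2L−2 = 0`); they receive
`c·max(2L−2, 1)` with a warning. The sum runs over distinct query terms —
term repetition inside a query is ignored, as short search requests rarely
repeat words meaningfully.

Summing the contributions places documents into score bins. Within a bin,
documents are ordered by `Σ tf(t,d)·idf(t)` over query terms present,
with `tf = 0.5 + 0.5·f(t,d)/max_f(d)` and `idf = log N/n_t` (natural log
by default; the base is config-exposed, though the within-bin
normalization makes it nearly immaterial). Raw tie values are divided by
a hair more than the bin maximum so every tie-break lies strictly in
(0, 1); a bin whose members all score zero receives a uniform epsilon and
falls back to doc_id order. Raw sums are quantized at 12 decimals so
floating-point summation noise cannot flip the deterministic doc_id
tie-breaking.

The emitted scalar score is `bin + tie_break · min(1, smallest bin gap)`.
With integral parameters and unexpanded queries the gap is ≥ 1 and this is
exactly `bin + tie_break`; when expansion weights produce fractional bins
closer than 1 apart, the scaling keeps run-file scores monotone with the
(bin, tie-break) lexicographic ranking.

**Expanded terms.** How expansion weights enter the bin score is an open
design point; here they multiply `(w_d + w_q)`, so original terms
(weight 1) reduce to the plain formula and an expansion can never
contribute more than its parent would. Expanded terms inherit the
relevance class of their parent term.

## Query expansion

Each original term keeps weight 1 and contributes its k nearest
vocabulary terms by cosine similarity (default k = 10; ties at the cut
broken lexicographically), weighted by that similarity. Model 2
multiplies the weight of every *non*-key-relevant original term and all
its expansions by `(1 − l)` with loss factor `l = 1%` by default; "reduce
by the factor l" admits two readings, so `loss_mode="multiply"` (weight
× l) is one flag away. Model 2 with `l = 0` is exactly model 1.
Neighbour lookup happens on the surface forms stored in the embedding
table; retrieved candidates are re-normalized through the text pipeline to
match index terms, duplicates keep the maximum weight, and candidates that
collide with an original term are dropped. Out-of-vocabulary terms stay in
the query without expansions. An optional minimum-similarity cut-off
(default 0 = off) supports threshold-based expansion instead of, or on top
of, the neighbour count.

The embedding trainer is a compact numpy implementation of CBOW with
negative sampling (mean-of-context predicts the centre word against
unigram^0.75 noise), deterministic under a fixed seed, with the
operational defaults dim = 200 and window = 5. It is a convenience for
small corpora; tests exercise it only on toy text.

## DFR baseline

The baseline scorer is InL2 from the Divergence-from-Randomness family:
`tfn = f(t,d)·log2(1 + c_norm·avg_len/len(d))`, contribution
`weight(t)·tfn/(tfn+1)·log2((N+1)/(n_t+0.5))`. `c_norm` is the
term-frequency normalization parameter; 1 and 33 are the two documented
operating points.

## Categorization and boosting

Query classification is string matching: unigrams, 2-skip-2-grams and
3-skip-2-grams of the stemmed query (before search-intent-word removal, so
constraint words can participate in descriptor phrases) against descriptor
phrases of the 11 UniProt annotation categories plus *Clinical trial*.
The shipped descriptor table is a starter inventory and editable; the
clinical-trial keyword set (`inclusion`, `exclusion`, `criteria`,
`patients`, `subjects`, `stage`, `duration`, `study`) is matched on stems.

Dataset classification combines a trained multi-label classifier with a
keyword rule: any of `clinical` / `trial` / `clinicaltrial*` in the record
text assigns *Clinical trial* unconditionally. The classifier embeds
documents with TF-IDF followed by truncated SVD (latent semantic document
vectors) and scores classes with a single-hidden-layer MLP (sigmoid output
per class, threshold 0.5); it trains deterministically under a fixed seed
and pickles losslessly. The synthetic training fixtures use separable
class vocabularies; real annotated corpora will be far harder, and no
claim about real-corpus F1 follows from the tests.

Boosting multiplies the full score (bin + tie-break) of documents ranked
in the top `⌈top_fraction·n⌉` positions (default top 50%) whose class set
intersects the query's classes by `(1 + g)`, `g = 10%` by default, then
re-sorts with ties keeping the previous order. The gain applies once per
document regardless of how many classes match. "Top 50%" is read as
positional eligibility; documents below the cut always keep their exact
score.

## Fusion

`score = α·norm(score_A) + (1−α)·norm(score_B)` per query over the union
of the two lists (missing documents count 0), α = 0.5 by default. Because
the fused runs come from scorers on different scales (DFR vs. RTRL), the
default normalization is per-query min-max; `norm="none"` reproduces raw
summation. A degenerate constant-score list normalizes to all-ones.

## Evaluation

Grades follow the challenge convention: 2 relevant, 1 partially relevant,
0 not relevant, −1 pooled but never judged; documents absent from the
qrels ("unpooled") are distinct from −1 and count as not relevant. P@10 is
reported counting grade 1 as relevant (+partial) and as not relevant
(−partial). NDCG uses linear gain = grade (the grades already are the
challenge's weights; exponential gain is a config option) and 1/log2(r+1)
discounts, with the ideal ranking drawn from the full pool.

For incomplete pools, three `unjudged_mode`s:

* `sampled` (default) — the judged entries of a query's pool are treated
  as a uniform sample of the pool. infAP estimates the precision above
  each judged relevant rank k as
  `E[P@k] = 1/k + (pooled/k)·(rel+ε)/(rel+nonrel+2ε)` (ε = 1e-5,
  config-exposed), where `pooled` counts pool members above rank k and
  rel/nonrel split the judged ones; unpooled documents above count as
  non-relevant with certainty, i.e. they dilute `pooled/k` but stay out of
  the sampled stratum. The estimate averages over judged relevant
  documents. infNDCG scales each judged gain by the inverse per-query
  sampling rate (judged/pool) at its observed rank and normalizes by an
  ideal DCG in which each judged positive document likewise stands for
  1/rate pool entries (fractional rank units integrate the discount).
  These are this package's exact semantics; no bit-compatibility with any
  external evaluation tool is claimed. Both estimators reduce to the
  exact metrics under complete judgments (within ε) — the test suite
  verifies this on 500 random rankings — and mean infAP recovers the
  fully judged AP to within 0.05 at 50% subsampling.
* `zero` — grade −1 becomes grade 0; exact metrics on the result.
* `remove` — grade −1 documents are removed from the ranking and pool;
  exact metrics on the remainder. Removing unjudged documents can only
  move relevant ones up, so `remove` dominates `zero` for AP.

Queries with no (judged) relevant document are excluded from means, with
the exclusions reported. AP-style relevance uses grade ≥ 1 by default
(`rel_threshold` exposed).

UIR (Unanimous Improvement Ratio): for systems A, B over shared test
cases, count cases where A ≥ B on every measure with at least one strict
win (N_A) and symmetrically N_B; UIR = (N_A − N_B)/cases; a system's score
is its mean pairwise UIR. Test cases default to queries
(`mode="per_query"`); `mode="single_vector"` compares the mean-measure
vectors, since either aggregation is defensible.

## Synthetic study conditions

The generator builds, from one seed: a DOC-format corpus (default 300
records), queries (default 8, three content terms each, phrased with
search-intent filler), graded qrels and a planted embedding table.
Background text is Zipf-distributed (exponent 1.1) so median-based key
relevance meets realistic frequency skew; repository sizes are drawn
heavy-tailed so a few repositories hold most records, mirroring real
dataset indexes. Per query: 12 relevant documents (all terms, repeated,
plus a synonym of each), 8 partially relevant (a majority of terms; every
fourth holds all terms but is graded 1 — grades are human judgments, not
term-count functions), 10 judged non-relevant distractors (one term, or
term-wise identical to a majority partial), and 20 further judged
non-relevant documents. Synonym-group embedding vectors sit within cosine
≥ 0.9 of an orthogonal group centroid with cross-group cosines ≤ 0.3,
making nearest-neighbour expectations exact.

These conditions are deliberately separable: they validate the machinery
(scoring equations, estimator reductions, pipeline identities), not
retrieval quality on real corpora. Near-ceiling metric values on the
fixture say nothing about performance on an 800k-record index with
pooled human judgments. Problem sizes in the tests and acceptance script
(200 random corpora of ≤ 50 docs for oracle agreement, 100 planted spaces
for expansion, 100 subsampling replicates) were chosen as the smallest
scales at which the checked properties are meaningfully exercised.

## Known limitations

* The general stopword list is a standard English list; any specific
  deployment's list will differ, which shifts document lengths and dfs.
* Expansion operates per term, not per query; no clustering or trained
  similarity cut-off.
* The dataset classifier's LSA + MLP route is a pragmatic stand-alone
  document embedder; paragraph-vector style embeddings trained jointly
  with the corpus would behave differently.
* infNDCG's inverse-rate gain scaling is a first-order estimator; its
  variance grows quickly below ~30% judgment coverage.
* Fusion supports exactly two runs; no rank-based (RRF/Borda) variants.
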