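# Methods

## The statistical model

The pipeline treats a bibliographic corpus as an urn. For one gene, the *m*
documents that mention it are regarded as a draw of size *m* from the *N*
documents of the corpus; if mentions were unrelated to the disease, the
number *k* of those documents that also mention the disease (*n* documents in
total) would follow the hypergeometric distribution with parameters
(*N*, *m*, *n*). The association statistic is the inclusive upper tail
P(X ≥ k); a small value means the joint mentions are too many to be
explained by chance co-occurrence. The same statistic is applied at two other
places with different counting units:

- **gene–gene co-citation**: sentences instead of documents (N′ = total
  sentences, m′, n′ = sentences mentioning each gene, k′ = sentences
  mentioning both);
- **gene-set enrichment**: genes instead of documents (background size,
  term size, query size, overlap), where the tail equals the one-sided
  Fisher exact test on the 2×2 overlap table.

Counting is always binary per unit: a document (or sentence) counts once for
a term no matter how many mentions it contains.

**Tail convention.** The inclusive tail P(X ≥ k) is the default: it is the
standard over-representation convention and the conservative choice; the
strict tail P(X > k) is available via a flag everywhere the statistic is
exposed.

**Multiplicity.** Significance defaults to raw P < α with α = 0.05 at every
stage — association filtering, enrichment, co-citation edge calling — which
is the convention this style of analysis historically used.
Benjamini–Hochberg FDR control is implemented (`correction="bh"`) but off by
default so the default behavior matches the raw-threshold convention.

**Numerics.** The tail is evaluated in log space: the pmf at the lowest
contributing overlap via log-gamma, subsequent terms by the ratio recurrence
pmf(i+1)/pmf(i) = (m−i)(n−i) / ((i+1)(N−m−n+i+1)), and the sum by
max-shifted exponentiation. This is overflow-free to N ≈ 10⁷ and agrees with
exact big-integer enumeration to well under 10⁻¹² across the entire
parameter space with N ≤ 60 (verified exhaustively in the test suite).
k = 0 returns exactly 1.

## Mention tagging

The tagger is a deterministic dictionary matcher, not a trained recognizer:
determinism makes every downstream count reproducible and testable, and the
lexicon is an input so recall is entirely user-controlled. Matching is
token-boundary anchored over alphanumeric tokens, case-folded, with
hyphen/space equivalence (inter-token gaps of up to three characters drawn
from space/hyphen), longest match first. Aliases that collide across genes
after normalization are dropped at load time; a stop-list file can remove
aliases that collide with common English words.

Conjunction resolution covers a finite, documented pattern family: a letter
stem with a numeric or single-letter designator followed by coordinated
elided designators introduced by `,` `/` `and` `or` (e.g. `IL-2, -4 and -6`,
`VEGF-A/B`). Every expansion is validated against the lexicon before
emission, so the patterns can be permissive without harming precision; the
span of an expanded mention points at its eliding fragment. Coordination
styles outside this family are left untouched.

Titles are treated as one sentence and scanned by default (a flag disables
this); the abstract is segmented by a rule-based splitter (terminal `.` `!`
`?` followed by whitespace and an uppercase letter or digit, with an
abbreviation guard list), which is idempotent and covers all non-whitespace
text with ordered, disjoint intervals.

## Network construction and topology

Edges from all evidence channels are merged into one **undirected** graph
deduplicated by gene pair; a pair supported by several channels becomes a
single edge carrying the union of relation types and all evidence records
(source tag, subtype detail, co-citation p-value). Directionality of
gene-expression relations is kept only as evidence metadata, because degree
and hub analysis treat connections symmetrically. Co-citation edges require
k′ ≥ 2 supporting sentences (configurable down to 1) to suppress
single-sentence coincidences.

The degree histogram is fitted two ways:

- **log–log least squares** (default): γ = −slope of log count vs log
  degree over degrees ≥ d_min with nonzero counts, goodness = R². Matches
  the straight-line presentation this analysis style uses, but is known to
  be statistically biased.
- **discrete MLE**: γ̂ = 1 + n·(Σ ln(dᵢ/(d_min−½)))⁻¹ with a KS goodness
  statistic; `d_min="auto"` selects the tail cutoff minimizing the KS
  distance, the standard remedy when a distribution is power-law only in its
  tail (as preferential-attachment degree distributions are: fitted from
  d_min = m the MLE underestimates γ, while KS-selected cutoffs recover
  exponents near the theoretical γ → 3).

A fit with non-positive exponent is flagged non-power-law. Fits require at
least three distinct supported degrees.

**Hubs** are selected by degree with three rules: `top_k`, `top_fraction`
(default 0.05 — with ties at the cutoff always included, ranking by degree
descending then gene id), and `degree_threshold`. The 5 % default mirrors
the proportion of hubs to nodes this kind of analysis typically reports.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
linguistic realism. Each document is independently disease-positive with
probability π_d; each gene is mentioned with probability π_g, lifted to
min(1, ρ·π_g) in disease documents for the planted gene set (mentions
independent across genes given disease status, matching the hypergeometric
null). A single planted scale-free interaction graph — preferential
attachment with a seed dyad and m_attach edges per arriving node, giving
1 + 2(n−2) edges for m_attach = 2 — is realized through **both** evidence
channels: partitioned uniformly into ECrel/GErel (KGML) and PPrel (TSV)
relation files, and as one-sentence co-mentions of a randomly chosen planted
edge in a fraction of documents. A configurable fraction of documents emits
two of its mentioned genes as a conjunction pattern (`GEN-3/7`) to exercise
the resolver on every run.

Default study conditions (the benchmark used throughout the tests and the
acceptance script): 5000 documents, 500 genes, π_d = 0.2, π_g = 0.01, 20
planted genes at ρ = 8, m_attach = 2, co-mention fraction 0.35, conjunction
fraction 0.10. Under these conditions the exact per-gene power of the
hypergeometric filter at α = .05 — computed by enumerating the binomial
mention counts in disease and background documents — exceeds 0.9999, so
planted-gene recall is expected to be 1.

Everything derives from one mandatory seed through independent named RNG
streams per stage; identical configuration therefore yields byte-identical
files, and the stored truth (realized per-gene document counts, planted gene
and edge sets) is reproduced *exactly* by recounting the corpus with the
real pipeline — the generator's core self-consistency contract.

What the generator does **not** model: abbreviation definitions, species
ambiguity, mention-frequency burstiness within documents, citation dynamics,
MeSH structure, or temporal trends. Passing tests therefore demonstrate
correctness of the counting and inference machinery under the model's
assumptions, not NER recall on real prose — on real abstracts, recall is
bounded by lexicon coverage and dictionary-matching precision.

## Pipeline and determinism

One config drives all stages; every run writes a manifest with the config
content hash, seed and per-stage in/out counts (documents → mentions →
scored genes → significant genes → network nodes/edges/hubs). Outputs carry
no timestamps and all orderings are total (p-value ascending with k-then-id
tie-breaks; canonical pair order for edges), so re-running a manifest
reproduces every artifact byte-identically. Stages write only into their own
subdirectory; enrichment is skipped with a logged notice when no annotation
files are configured; an empty significant-gene set degrades the network
stage to the unrestricted evidence union (co-citation over all mentioned
genes) rather than failing.

## Design choices on genuinely open points

- **N is the size of the supplied corpus**, which is expected to contain
  disease-negative documents; if the corpus were only disease-query hits,
  n = N and the statistic degenerates. The generator produces both kinds.
- **Gene–disease counting is document-level; gene–gene co-citation is
  sentence-level.** Publication-frequency association and within-sentence
  co-mention are different evidence types and get different granularities.
- **Network edges are deduplicated by pair** (multi-evidence pairs count
  once), with provenance preserved per evidence record.
- **Background universe for enrichment** defaults to annotated genes rather
  than the whole lexicon, avoiding p-value deflation from unannotatable
  genes; overridable.
- **Problem sizes in the test suite** (300–5000 documents, 60–500 genes,
  5–20 seeds per Monte-Carlo check) were chosen as the smallest sizes at
  which the binomial/Monte-Carlo error bands in the acceptance properties
  are informative.

## Known limitations

- Dictionary NER cannot find genes absent from the lexicon and does not
  disambiguate aliases shared with common words beyond the stop-list.
- GO annotations are used as given — no propagation to ancestor terms along
  the GO DAG (a documented extension point).
- The least-squares power-law fit is biased; it is retained as the default
  for comparability with the histogram-regression presentation, with the
  MLE mode as the statistically preferred alternative.
- Betweenness/eigenvector centralities and community detection are out of
  scope; hub selection is degree-based only.
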