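# Methods

This note records the models and procedures termspace implements, the
defaults that matter, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Corpus model and tokenization

A document is (id, calendar year, title, abstract, language tag); title
and abstract are distinct text units and window statistics never cross the
boundary between them. Title and abstract are otherwise pooled — nothing
in the statistics weights them differently. Documents whose year falls
outside the configured window (default 1900–2100) are retained but
flagged; every statistics operation takes an explicit year range instead
of silently dropping them.

Tokenization: Unicode NFC, lowercase, punctuation outside words dropped,
single intra-word hyphens kept. A hyphenated compound is emitted once
joined and once per part (`non-small-cell` → `non-small-cell, non, small,
cell`), so both granularities are visible to window statistics. This
makes strict sequence idempotence under space-rejoining impossible (the
parts would re-duplicate); what holds, and what the property tests
assert, is idempotence of the token *set*, plus exact sequence
idempotence for hyphen-free text.

MEDLINE-style XML is read as a minimal subset (PMID, ArticleTitle,
AbstractText, PubDate); the year is the first 4-digit run inside PubDate,
which tolerates `<MedlineDate>2007 Jan-Feb</MedlineDate>`-style dialects.
Records with no parseable year abort the load with the record position —
nothing is dropped silently.

## Neighborhood discovery

For every token matching a key root, every other token within `window`
positions in the same field that is itself outside the key dictionary is
recorded as a candidate, one count per co-occurrence event (not per
document — the per-document convention is used only by the yearly count
table, where it belongs). Phrases are stored as ordered pairs in textual
order. First year and per-year counts are kept so novelty can be assessed
downstream; "new word" deliberately means "not in the key dictionary",
with no date precondition.

Defaults: window 5 tokens each side, selection threshold 5 with strict
inequality (a candidate must exceed the threshold). Both are configurable
and echoed into output metadata. Stopword-only candidates are *not*
filtered here — single responsibility; the collocation classifier removes
them.

Promotion takes the discovery table as an explicit argument so the
"accepted surfaces must have been seen" precondition is checkable without
hidden state; it is append-only and idempotent, and attaches each
accepted surface under every root it was discovered with.

## Trend statistics

* Trend ratio: smoothed relative-frequency ratio with the constant 0.1 in
  all four positions. The constant is part of the statistic and is not a
  tuning parameter; it guarantees a finite positive value for any
  non-negative counts (absent-in-both-years gives exactly 1.0).
* Relative growth: `100·(N_f − N_b)/N_f`. The form is fixed by its
  boundary behavior: exactly 100.00 for a term absent at baseline, 0 at
  no change, negative on decline, bounded above by 100. Baseline 2007 and
  final 2019 are defaults only. Counts are single-year document counts
  (a document counts once per term per year), not pooled multi-year
  windows.
* Polynomial trend: ordinary least squares of degree 3 by default. Years
  are mapped to [−1, 1] internally (numpy's domain mapping — equivalent
  to centering and scaling) for conditioning; coefficients are reported
  in the original year basis. R² = 1 − SS_res/SS_tot; the residual SD is
  the population (ddof = 0) standard deviation of the fit residuals,
  i.e. the ± band one quotes alongside an extrapolated value. A constant
  series is rejected (R² undefined), as is a fit with ≤ degree distinct
  years.

## Derivatives, collocations, categories

A word derives from a root iff it is the root, or optional-prefix + stem
+ optional-suffix where the prefix is one of {un, non, de} (covering the
attested derivative inventory; extendable) and the stem reproduces the
root letter-for-letter up to the s/z interchange. The interchange makes
British/American orthography (`personalise`/`personalize`) one family by
construction.

Collocation classes partition into: random (either member matches the
stop-pattern list — auxiliaries, generic adverbs, determiners,
prepositions; shipped as an editable resource file since only examples,
not a list, are attested), megatoken-forming (both members map to
megalemmas; the megatoken is attached), else independent.

Categories are positional over the configured roots (default `predict,
personali, prognos, prevent`): the first two roots split into derivative
and megatoken categories (indices 1/2 and 3/4), the last two get one
mixed category each (5, 6) because those families are too small to split.
The (index, color) pairs are fixed: purple, green, black, blue, red,
yellow. Items classified random are excluded from the map and cannot be
categorized.

Where a summary reports megatoken statistics it exposes both the number
of megatokens and the number of member collocations; the two counts are
genuinely different quantities and neither is the "right" one.

## Megalemmas and megatokens

Storage order for megatoken labels is case-insensitive lexicographic —
the only order that makes equality order-invariant — while display is
root-first (`GEN + DISEASE`, `PREDICT + MODEL`), matching how such units
are conventionally printed. Both renderings are derived from the same
stored tuple; nothing is stored twice.

The reverse index is keyed by (surface, language): one surface maps to at
most one megalemma within a language, while identical spellings across
languages may map differently. The dictionary file is TSV (label,
surface, language) with `#` comments; megatoken rows reuse the label
column with `+`-joined labels. The dictionary also carries the set of
known megatokens because text normalization must know which adjacent
label pairs merge; this is the one extension beyond the obvious record
types.

Text normalization maps tokens through the dictionary (hyphenated
compounds looked up whole), merges adjacent mapped pairs that form a
known megatoken (greedy left-to-right), omits unmapped tokens from the
sequence, and reports coverage = mapped/total tokens (0 for empty text).

Merge proposals require both signals: cosine(word vector, member
centroid) > 0.7 *and* Jaccard(megalemma-label context sets) > 0.3, ranked
by cosine with context score and label as tie-breaks. The thresholds are
defaults for "very similar" — no principled values exist, so they are
configurable and recorded. Context sets are built by an explicit helper
(`build_context_sets`) rather than hidden inside the proposal function,
keeping it a pure function of its inputs. Embeddings are consumed (plain
text table, optional word2vec-style header), never trained. Machine
translation of member forms is out of scope; the dictionary is supplied
or grown via proposals.

## Scene construction

Rating = window occurrence count ("rating" has no attested definition;
occurrence count is the one quantity every table orders by, and
alternative weightings are config options recorded in scene metadata).
Radius = 0.1 + 0.25·log(1+rating): strictly monotone in rating and keeps
a 629-count and a 5-count term co-visible. Layout: PCA (full SVD,
deterministic sign convention) to three axes after centering; input that
is already ≤ 3-dimensional is centered and zero-padded, not rotated, so
3D input passes through. Identical vectors get identical coordinates
(`fit` + `transform`, not `fit_transform`, which returns U·S and is not
row-wise reproducible for duplicate rows). Box scaling to [−10, 10]³
happens at scene assembly, not inside the projection. Export is
deterministic byte-for-byte: nodes sorted by label, floats rounded to 6
decimals, JSON keys sorted. Edges between spheres are omitted: no edge
construction rule is attested, so none is invented.

## Synthetic corpus

The generator states a world and the tests measure it; its parameters are
not tuned against outcomes. Background text: Zipf rank-frequency
distribution (exponent 1.1) over a 1,000-word vocabulary, abstract length
Poisson with mean 120 tokens (floored at 10) — realistic sparsity for
window statistics at abstract scale. Default 60 documents per year.
Injected terms follow an exact per-year document schedule (the term
appears once per scheduled document); collocation partners are placed
adjacent to the term with the stated probability; segments are separated
by a 10-token filler gap so each partner co-occurs only with its own term
for any window ≤ 10, making the returned pair counts exact by
construction. Bilingual fixtures emit one hidden megalemma-label sequence
through per-language surface tables.

A green test on this corpus establishes that the counting, trend and
discovery machinery is correct against construction-time ground truth. It
does not establish linguistic realism: there is no grammar, no topical
coherence, no morphology in the background vocabulary, and no
polysemy — conclusions about real corpora still require real corpora.

## Known limitations

* Neighborhood counts are per event; document-level co-occurrence counts
  would differ for terms repeating within one abstract.
* The derivative rule is orthographic; it cannot separate true morphology
  from accidental string prefixes beyond the stem check (e.g. it relies
  on roots being chosen sensibly).
* Russian is handled lexically via the megalemma dictionary; no
  morphological analysis is attempted.
* The scene records no edges between related terms.
* Headline corpus-scale figures (absolute counts per key root and the
  fitted activity curve on a real bibliographic database) depend on that
  database and are outside what the desk-scale synthetic world can
  reproduce; the tests verify the statistics, not those figures.
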