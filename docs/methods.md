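# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
where the design was genuinely open.

## Corpus model and cleaning

A record is one publication with text fields (title, abstract), a year, a
document type, entity lists (authors, institutions, countries, author and
indexed keywords) and a citation count. Input is a Scopus-style CSV
export: quoted fields, `"; "`-delimited multi-value cells (delimiter
configurable). Countries and institutions are taken from explicit columns
when present, otherwise parsed from affiliation strings — institution =
first comma token, country = last comma token matched against a shipped
gazetteer of 60 country names. Rows with an unparseable year are routed to
a rejects report, never silently dropped. Files are read as UTF-8 with
invalid bytes replaced.

**Deduplication key.** Databases rarely document their dedup rule, so the
package fixes one: records sharing a DOI are duplicates; DOI-less records
are keyed by (lowercased, punctuation-stripped, whitespace-collapsed
title, year). Among duplicates the record with the larger citation count
is kept (ties: first occurrence) — deterministic, and it preserves
citation-based indicators. Deduplication is idempotent.

**Name normalization** is an explicit variant → canonical alias map per
entity level, validated for idempotence (canonical names map to
themselves). Unmapped strings pass through and are reported. No fuzzy
author disambiguation is attempted.

## Bibliometric conventions

* **Whole counting.** Every distinct entity listed on a record receives
  one full publication credit. Country shares of a multi-country corpus
  therefore sum above 100% — the convention that reproduces published
  country tables.
* **Rounding.** Shares (`100·count/total`) and citation ratios
  (`citations/publications`) are rounded *half-up* to the printed number
  of decimals (1 by default); Python's banker's rounding would turn 88.45
  into 88.4 where reports print 88.5. A zero publication count raises an
  error rather than returning a silent 0.
* **Ranking ties** are broken alphabetically so tables are reproducible.

## Networks

Nodes are entities weighted by publication count; edges are weighted by
co-publication counts; graphs are undirected with no self-loops (a record
listing an entity twice counts it once). The document-count threshold is
applied to nodes *before* edge construction, matching the convention "the
network of authors with at least five publications": the node set is fixed
first, then pairs among retained entities form edges.

Modularity is the weighted Newman–Girvan quality
`Q = Σ_c [w_c/W − (s_c/2W)²]`; the implementation is checked in the test
suite against an independent brute-force double sum over ordered node
pairs and against networkx's modularity. Community detection is Louvain
(local moving + aggregation) at resolution 1.0 via
`networkx.algorithms.community.louvain_communities`; the seed controls
node visiting order, making runs deterministic, and the returned score is
always recomputed from scratch with the package's own modularity function.
Community labels are canonicalized by each community's smallest member.
Edgeless graphs yield singleton communities with the modularity flagged
undefined (`None`) instead of a fake 0. Exports: GEXF, GraphML, or an
edge-list CSV (which does not carry node weights).

Two-period analyses (2002–2012 vs 2013–2022 by default) are plain drivers
that filter by year (inclusive bounds) and rebuild networks; there is no
special code path.

## TRL classification

Nine TRL levels are grouped into five categories visible in publications:
TRL1 (extract identification / basic research), TRL2 (isolation,
fractionation, chemical characterization), TRL3 (in vitro / in silico),
TRL4-5 (in vivo animal work, formulation, patent readiness — grouped
because patent activity is rarely visible in papers), TRL6-9 (clinical
trials of any phase, including population-response studies of traditional
use — grouped because phases are not separable from abstracts).

**Representations.** The literature on anchor-keyword classification
leaves open how a topic model and a set distance combine; the package's
design makes all four measures runnable in one argmin framework:

* *Set route (Jaccard).* Document = preprocessed token set, optionally
  unioned with the top-`top_m` words of every LDA topic whose θ weight is
  ≥ `theta_min` (defaults 10 and 0.25 when the expansion is used; `top_m=0`
  disables it, and then no topic model is needed). Category = its anchor
  token set. Jaccard distance `1 − |A∩B|/|A∪B|`.
* *Distribution route (Hellinger, KL, JS).* Document = its LDA topic
  distribution θ; category = θ inferred on the category's anchors
  concatenated as a pseudo-document. KL is smoothed with ε = 1e−10 and
  directed KL(document ‖ category); JS is computed exactly (in nats,
  bounded by ln 2); Hellinger is `(1/√2)·‖√p − √q‖₂`.

**Preprocessing** is deterministic: lowercase, alphanumeric tokens of
length ≥ 2, scikit-learn's English stopword list. Anchor bigrams such as
"in vitro" therefore match on their content tokens ("vitro").

**LDA** is batch variational EM (scikit-learn), K = 20, α = 1/K,
β = 0.01, 200 maximum sweeps, fixed seed. Two hundred sweeps is past
convergence for corpora of a few hundred abstracts; θ and φ rows are
normalized and verified to sum to 1 within 1e−8.

**Decision rule.** Prediction is the argmin of the five distances; exact
ties break toward the *lower* category — the conservative maturity claim.
Records whose abstracts are empty after preprocessing are counted as
unclassifiable, never guessed. The labeled benchmark (107 records by
convention) is used only for measure selection and expansion-parameter
sanity checks, with the fixed tie order jaccard → Jensen–Shannon →
Hellinger → Kullback–Leibler; anchors are never training labels.

**Shipped anchor sets.** One YAML file, config-replaceable, built from the
category definitions above. The shipped sets are token-disjoint across
categories, which gives each category an unambiguous token signature; the
test suite asserts this property because exact recovery on
disjoint-vocabulary corpora depends on it.

## Synthetic-corpus generator

The generator emulates the statistical shape of a two-decade bibliographic
corpus, with defaults chosen as the study conditions the package is
exercised under:

* **Volume**: years 2002–2022, weight 1 per year through 2010 then a
  linear ramp of slope 0.25 per year — ≈29% of records fall in 2002–2012,
  matching the roughly 30/70 split of such corpora, with the series
  maximum after 2010.
* **Countries**: one dominant country at 65.9% of the mixture, then 12.9 /
  6.9 / 5.5 / 5.0 / 3.8%; a second country is added with probability 0.25.
* **Authors**: 60 authors in 6 planted blocks; each record draws a home
  block, then co-authors from the home block with odds `p_in : p_out`
  (defaults 0.9 : 0.05). With `p_out = 0` the co-authorship graph's
  components coincide with the blocks exactly.
* **TRL labels**: i.i.d. from a five-category mixture with shares
  ≈ 1.4 / 45.1 / 4.5 / 25.1 / 23.9%.
* **Abstracts**: token soups of Poisson length (mean 60, min 30). Each
  abstract starts with `n_anchor_tokens = 3` tokens drawn from its true
  category's anchor set — the generator's definition of label signal —
  followed by tokens drawn from a shared background vocabulary with
  probability ε and from the category vocabulary (anchors + 40 filler
  terms) otherwise. ε = 0 makes category supports disjoint, so exact label
  recovery is guaranteed, not merely probable; ε = 1 leaves only the
  injected anchors informative.
* **Citations**: negative binomial (mean 15, dispersion 1) for a heavy
  tail; irrelevant to correctness tests.
* **Dirt**: 10 duplicates (half exact-DOI copies, half DOI-less
  title-case variants, exercising both dedup keys) and 8 author-name
  variants with a ground-truth alias map.

Identical parameters and seed give a byte-identical corpus file.

What the generator does **not** emulate: natural-language abstracts (no
syntax, no polysemy, no anchor terms used in non-anchor senses), citation
dynamics over time, institution-level collaboration structure beyond
country membership, and anchor sets that overlap across categories the
way real terminology does. Passing recovery tests therefore demonstrates
the pipeline's correctness — that each stage recovers exactly the
structure planted under its assumptions — not the field-realistic error
rate of the classifier, which on real abstracts is bounded by the quality
of the anchor sets.

## Problem sizes and runtime

The standard experiment sizes are 500-record corpora for benchmark runs
(five seeds, LDA K = 20), 150–200-record corpora for recovery curves
(Jaccard route, no LDA fit needed), ≤ 8-node graphs for exhaustive
partition-search oracles (Bell(8) = 4140 partitions), and 40-node
planted-partition graphs over 20 seeds for community recovery. These
sizes make every experiment reproducible on a single CPU in minutes while
keeping the statistical checks (binomial concentration of label marginals,
ARI of block recovery) well-powered.

## Known limitations

* Affiliation parsing assumes the Scopus "…, Country" convention; unusual
  affiliation formats silently yield no country (they remain visible in
  the record's institution list).
* The alias map is exact-string; no probabilistic record linkage.
* Jaccard ignores token frequency; abstracts dominated by one repeated
  anchor token are treated the same as balanced ones.
* Distribution-route categories depend on anchors being in the LDA
  vocabulary; categories absent from the corpus (rare classes in small
  samples) raise an explicit representation error rather than degrading
  silently.
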