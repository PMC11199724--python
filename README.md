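# herbametrics

Scientometrics of the medicinal-plant / herbal-medicine research
literature: corpus cleaning for Scopus-style exports, bibliometric
indicators, collaboration-network analysis with modularity communities,
and an unsupervised Technology Readiness Level (TRL) classifier for
abstracts.

## The problem

Bibliometric studies of a research field — here the literature on
medicinal plants and phytomedicines, dominated by one country and by
neglected-tropical-disease topics — typically need four analyses over one
cleaned bibliographic corpus:

1. **Cleaning.** Deduplicate records (DOI key first, then a normalized
   title + year key) and map author/institution/country/keyword name
   variants onto canonical forms through an explicit alias map.
2. **Indicators.** Annual publication series, ranked entity tables under
   *whole counting* (each listed entity gets full credit, so shares may sum
   above 100%), percentage shares, and citation ratios
   `CR = citations / publications`.
3. **Networks.** Co-authorship graphs at country/institution/author level
   (edge weight = number of jointly authored records, node threshold
   applied before edge construction) and keyword co-occurrence graphs over
   author + indexed keywords. Communities by Louvain optimization of
   weighted modularity

   `Q = Σ_c [ w_c / W − (s_c / 2W)² ]`

   with `w_c` the intra-community edge weight, `s_c` the community's total
   weighted degree, `W` the total edge weight.
4. **TRL classification.** The nine-level TRL maturity scale collapsed to
   five publication-visible categories (TRL1, TRL2, TRL3, TRL4-5, TRL6-9).
   Each category is anchored by a small keyword set; each abstract is
   represented either as its token set (optionally expanded with the top
   words of its dominant LDA topics) or as its LDA topic distribution θ;
   the predicted category is `argmin_c d(doc, c)` for a distance `d` ∈
   {Jaccard, Hellinger, Kullback–Leibler, Jensen–Shannon}, with ties broken
   toward the lower (less mature) category. A small hand-labeled benchmark
   is used only to select the distance measure, never to train.

Because real database snapshots are proprietary, the package ships a
synthetic-corpus generator with full ground truth (planted author blocks,
TRL labels, injected duplicates and name variants, controllable vocabulary
overlap ε) so every stage is testable end to end. See `docs/methods.md`
for the model details and design choices.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
500-record corpus and write their tables under `results/`:

```bash
python analysis/01_simulate_corpus.py      # corpus + ground truth
python analysis/02_clean_corpus.py         # dedup + alias normalization
python analysis/03_bibliometric_tables.py  # series, rankings, shares
python analysis/04_collaboration_networks.py
python analysis/05_trl_classification.py
python analysis/06_full_pipeline.py        # one-config end-to-end bundle
```

Selected output (seed 42):

```
510 rows in; 10 duplicates removed; 500 kept (input = kept + removed: True)

top countries (whole counting):
  Brazil           345 records ( 69.0%), citation ratio 15.3
  United States     88 records ( 17.6%), citation ratio 13.9

full_author          60 nodes   465 edges Q=0.7192
author community vs planted blocks: ARI = 1.0

per-measure benchmark error (107 labeled records):
  jaccard             0.0%
  hellinger          21.5%
selected measure: jaccard

TRL distribution of the classified corpus:
  TRL1       8    1.6%
  TRL2     221   44.2%
  TRL3      21    4.2%
  TRL4-5   128   25.6%
  TRL6-9   122   24.4%
```

Reading: the cleaner removed exactly the 10 injected duplicates; the
dominant country carries ~66% of records (whole counting lifts its listed
share to 69%); Louvain recovers the planted author blocks perfectly
(ARI 1.0); the Jaccard set distance clearly beats the three
topic-distribution distances on the labeled benchmark, and the resulting
five-category TRL distribution matches the generator's target mixture
(~1 / 45 / 4 / 25 / 24 %).

The same steps are available as a CLI:
`herbametrics simulate|clean|metrics|network|trl|run --help`.

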