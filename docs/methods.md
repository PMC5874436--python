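# Methods

## Problem and model

The package detects forum posts in which a patient describes deviating
from a prescribed treatment — stopping the drug or changing its dose —
given only a corpus of posts that mention the drug. The core model is
latent Dirichlet allocation (LDA): each post `d` mixes `K` topics with
proportions `θ_d`, each topic `k` is a distribution `φ_k` over the
vocabulary, and each token is drawn topic-first, word-second. Posts whose
token mass concentrates on a topic whose vocabulary reads as "stopping
treatment" or "changing dose" are flagged for human review. The approach
is deliberately high-recall / low-precision: it shortlists candidates,
it does not classify.

## Preprocessing

Six steps, in order: dosage standardization, lowercasing + punctuation
stripping, stopword removal, drug-name removal, stemming, n-gram
construction.

- **Dosage standardization runs first**, before tokenization, because the
  pattern (`number`, optional space, unit) spans a space; every match
  becomes the protected token `dosemilligrams`. Decimal commas and points
  are both accepted; the unit list (mg, g, ml, µg, spelled-out variants)
  is configurable.
- **Tokenization** lowercases and replaces every character that is not a
  Unicode letter or digit with a space. Apostrophes therefore split
  French elisions (`l'arrêt` → `l`, `arrêt`); the elision fragments are
  in the default stopword list.
- **Stopwords**: a standard French function-word list ships with the
  package (`data/stopwords_fr.txt`) and is fully overridable. No list is
  canonical; any reasonable French list gives equivalent downstream
  behavior because LDA ignores terms that the sparsity filter removes.
- **Drug-name removal** is exact-match on the configured brand/INN names.
  The drug name appears in every post of a drug-defined corpus, so it
  carries no information. Misspellings are retained — fuzzy matching is
  out of scope.
- **Stemming** uses the French Snowball algorithm, implemented in
  `_snowball.py` because no stemming library exists in the dependency
  stack. The implementation follows the published algorithm (marking
  prelude, RV/R1/R2 regions, standard/verb/residual suffix steps,
  undoubling, unaccenting) and is pinned by hand-traced reference stems
  in the test suite. Corpora are French; no other language variant is
  shipped.
- **Bigrams** are formed after filtering and stemming, over the resulting
  adjacency, and joined with `_`. Collocations such as
  `effet_secondair` (adverse effects) then behave as single vocabulary
  items.

## Document-term matrix and vocabulary selection

Counts are integer occurrences; per-term sparsity (share of documents
lacking the term) and overall sparsity (share of zero cells) are computed
on presence/absence. The vocabulary scan walks candidate per-term
sparsity thresholds from 0.9995 down to 0.80 in steps of 0.00025,
dropping every term rarer than the candidate allows, and stops at the
first candidate whose reduced matrix has overall sparsity at or below the
target (default 0.97). The target is crossed from above, so achieved
sparsity lands slightly below 97%; this removes the long tail of
misspellings, rare abbreviations and one-off bigrams. Documents emptied
by the filter are dropped and reported. TF-IDF weighting
(`tf/row_total × log2(D/df)`) is provided; when a weighted matrix is
passed to the fitter, weights are mapped to pseudo-counts as
`round(10 × weight)` because the multinomial likelihood needs count-like
data. The default pipeline fits on counts.

## Estimation

MAP-EM maximizes the log posterior
`Σ x_dv log Σ_k θ_dk φ_kv + (α_θ−1) Σ log θ + (α_φ−1) Σ log φ`.
Defaults `α_θ = α_φ = 1.1` keep the mode strictly interior (any value
> 1 behaves similarly; 1.1 imposes minimal smoothing). The E-step/M-step
updates are closed-form and each sweep is monotone in the objective; the
per-iteration trace is stored and asserted non-decreasing in the tests.
Convergence is relative change below `tol` (default 1e-6) or `max_iter`
(default 300). Restarts (default 2) redraw `φ` rows from a symmetric
Dirichlet(1.5) with seeds `seed + i`; **`θ` is initialized uniform**, not
random, so that the fit is equivariant under document reordering (theta
rows permute with the documents, phi is unchanged) — a property the tests
verify exactly and that a per-row random initialization would break.
M-step numerators are floored at 1e-12 before normalization; with
α > 1 the floor never binds.

## Choosing the number of topics

The log marginal likelihood is approximated BIC-style: maximized log
posterior minus `(df/2)·log N`, with `df = K(V−1) + D(K−1)` free
parameters and `N` the total token count. The log Bayes factor against
the one-topic model, `BF(K) = log m(K) − log m(1)`, is computed for each
K on the grid (the K = 1 baseline is always fitted, so `BF(1) = 0`
exactly); the argmax wins and K = 1 is kept when every `BF ≤ 0`. Any
consistent penalized-likelihood surrogate preserves these comparison
semantics; the BIC penalty is conservative — on small corpora with
bigram-inflated vocabularies it tends to under-segment (select fewer
topics than planted), which is acceptable here because flagging only
needs the noncompliance vocabulary to surface in *some* selected topic,
not a perfect segmentation.

## Assignment, labeling, extraction

Token-level topic association is not uniquely determined by the model;
the package uses the MAP rule `argmax_k θ_dk φ_kv` (ties to the lowest
index), the simplest rule consistent with "tokens associated to a
topic". Repeated occurrences count multiply; out-of-vocabulary tokens are
excluded from the denominator. A message is associated with every topic
holding at least τ = 25% of its tokens, so a message carries at most
`⌊1/τ⌋ = 4` topics and raising τ can only shrink assignments. Topic
labels are human judgments supplied as a YAML/CSV map; the
distinguished labels are `treatment_cessation` and `dosage_variation`.
On synthetic corpora, `label_topics_by_markers` stands in for the
labeler: it reads each topic's 15 highest-probability terms (the same
first-terms reading a human uses) and labels the topic when at least 2 of
them are marker stems of a planted noncompliance vocabulary. Flagged
messages are reported per label, with their union and intersection.

## Evaluation arithmetic

Precision is `100·tp/flagged` per topic and recall `100·tp/(tp+fn)` from
a seeded 20% sample of the unflagged messages, both rounded half away
from zero to 1 decimal. The review sample size is `ceil(fraction × n)`
(e.g. 20% of 1723 → 345, of 3246 → 650). Headline multi-topic scores are
the **macro-averages** of the per-topic values (e.g. per-topic precisions
28.9, 46.3, 31.8, 23.4 → 32.6), not pooled ratios. Two-decimal corpus
rates are truncated toward zero (276/4469 → 6.17), matching the
convention of the protocol this package reproduces. Cohen κ uses the
standard 2×2 marginal-product chance correction and is cross-checked
against an independent implementation on random tables.

## Synthetic corpus generator

The generator emulates drug-defined French forum corpora at desk scale.
Defaults: D = 500 posts, 200 content words (`w000`…), K = 5 planted
topics with `φ_k ~ Dirichlet(0.08)` (topics concentrate on ~15 words),
document weights `θ_d ~ Dirichlet(0.15)`, Poisson(60) lengths. Topic 0
is treatment cessation and topic 1 dosage variation: each moves half of
its word mass onto a small French marker vocabulary (arrêter, stopper,
… / dose, diminuer, …); the dosage topic additionally emits literal
dosage strings ("10 mg", "2,5 mg") that only preprocessing can fold into
`dosemilligrams`. Rendered text inserts the drug name exactly once per
post, filler stopwords at rate 0.25 and sentence punctuation. A post is
**gold noncompliant** when its generative mass on a noncompliance topic
reaches 0.5 — truth comes from the generative weights, never from text
patterns.

The document concentration 0.15 was chosen so that messages assigned
under the 25% rule carry ≈ 1.2 topics on average, the regime observed on
real drug forums; sharper or flatter mixing changes how much structure
the Bayes factor can afford to segment. What the generator does **not**
emulate: French grammar and word order (bigrams are random adjacencies,
not collocations), misspellings, annotator disagreement, near-duplicate
reposts, and topic correlations. Passing tests therefore demonstrate that
the pipeline machinery is correct and that the protocol's recall property
holds under its own generative assumptions — not that the precision
observed on real forums will be matched.

## Numerical and interface choices

- Topic indices are 0-based everywhere (arrays, reports, label maps).
- Dates are parsed as opaque ISO-8601 strings; the method uses no time
  information.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  corpora and fits.
- `top_terms` breaks probability ties alphabetically, making reports
  deterministic.
- Degenerate inputs fail loudly: empty corpora, all-zero document rows
  (with a pointer to `drop_empty_documents`), unknown terms, invalid
  thresholds.

## Problem sizes

The shipped tests and the acceptance script run the benchmark at
D = 400–500 documents, vocabularies of 150–220 generator words
(≈ 2000 DTM terms after bigrams), K grids up to 8 and 10–20 seeded
replicates — sizes at which the full suite completes in a few minutes on
one CPU while leaving the statistical properties (topic recovery,
selection consistency, end-to-end recall) comfortably testable.

## Known limitations

- The BIC-style marginal approximation is one of several defensible
  surrogates; absolute `BF` values are not comparable across corpora.
- The 25% association rule and the 97% sparsity target are protocol
  constants, not optimized quantities; the package exposes both.
- Only the French Snowball stemmer is shipped; other languages require a
  stemmer plug-in.
- Real-corpus precision depends on discourse phenomena (other
  experiencers, hypothetical/planned changes, other substances) that no
  bag-of-words model separates; the flags are review input, not
  decisions.
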