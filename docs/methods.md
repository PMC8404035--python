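# Methods

This note documents the models and procedures `ontomine` implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Corpus model

A corpus is a flat set of posts grouped into threads within forums. The
post at position 0 is the thread's opening post; the first-post indicator
derived from it is the central covariate of the sentiment model. Threads
with zero posts are tolerated on read (some forums expose empty topics) but
excluded from summaries, binning and mining, since they carry no text.
Posts-per-thread standard deviations use the sample (n−1) denominator;
at the 1-decimal precision of the reported summaries either denominator
gives the same figures. JSON Lines is the canonical serialization — forum
text contains commas, quotes and newlines, which JSONL carries trivially —
with CSV (quoted, UTF-8) as an interchange convenience.

## Text normalisation

Tokenization lowercases and splits on any character outside `[a-z0-9]`.
Hyphenated drug names therefore split into their parts, and numerals
survive (grading terms like "grade 1" are clinically meaningful). Stopwords
are removed before stemming from an editable plain-text list: a standard
English function-word list extended with forum pleasantries ("thanks",
"xx", "hi"). Remaining tokens are stemmed with the classic Porter
algorithm, implemented here from the published rule tables (so "pained",
"painful", "pains" all become "pain"; "hospital" becomes "hospit"). Porter
is not idempotent on every English word; the test suite checks the
fixpoint property over the generator vocabulary specifically, which is
chosen to be stem-stable, and the property test reports any exception
rather than hiding it.

## Synonym mining

**Stratified split.** Threads are sorted by size and cut into three
equal-frequency bins (near-equal thread counts; the remainder goes to the
smallest-size bins), and a random 20% of threads is drawn for the test
partition. The per-bin test quota is the largest-remainder allocation of
floor(0.2 · n_threads) around each bin's proportional share, which keeps
every bin within one thread of floor(0.2 · bin size) while hitting the
global count exactly. If the corpus is so small that the global floor is
zero, one thread per bin is taken, with a warning.

**Document unit.** Each training thread becomes one document (posts
concatenated in position order, then normalised). Threads are the
observational unit of the split and the binning, so they are the default
document; per-post documents are available by configuration.

**Ranking.** For term t in document d: idf(t) = ln((1+N)/(1+df(t))) + 1,
weight w(t,d) = tf(t,d) · idf(t) with raw counts, and the corpus score is
max_d w(t,d) (sum available by configuration). No vector normalization is
applied, deliberately: the review threshold of 1.0 only has meaning on raw
scores — a term occurring once in every document scores exactly 1.0, so
"score > 1.0" means "rarer than ubiquitous, or repeated within a
document". The weighting is computed by scikit-learn's `TfidfVectorizer`
(`norm=None, smooth_idf=True`), which implements exactly this formula; the
test suite checks it against an independent brute-force evaluation.
Maximum was chosen over sum as the cross-document aggregate because it is
insensitive to corpus size, which keeps the 1.0 threshold meaningful for
corpora of any size.

**Curation loop.** Every above-threshold term not previously decided goes
to the curator. Decisions are: attach to an existing class (with explicit
surface forms — the curator, not the engine, consolidates misspellings
back to correctly spelled variants), create a new class, or reject.
Accepted stemmed terms are removed from all documents before the next
ranking so remaining terms re-weight; rejected terms go on a persistent
reject list and are never re-surfaced. The loop terminates at the first
round with zero accepts (termination reason `no-accepts`) or after
`max_rounds` (default 10). Progress is guaranteed: every round either
accepts (shrinking the vocabulary) or stops. A `ReplayCurator` replays a
decision TSV, which both makes expert sessions reproducible and lets tests
drive the loop from ground truth.

**Split validation.** After mining, the test partition is ranked
identically and its above-threshold terms compared with the accepted set
and the training ranking; terms seen only in the test partition are
reported as candidate misses.

## Ontology store

Classes carry a CURIE id, a label, provenance-tagged synonyms (scope:
exact/narrow/broad/related/unspecified — unspecified is the default since
synonym scoping is a curation refinement, not a mining output), database
cross-references (SNOMED-CT, ICD-10, Read, DOID, HPO, ORDO, PATO, UBERON,
…), is-a parents, constructed relationships (part-of, adjacent-to,
investigated-by, treatment-of, occurs-in, characterised-by), and
equivalence/disjointness axiom pairs. Axioms are stored as annotations and
checked structurally (a class may not be both equivalent and disjoint to
the same target); no description-logic reasoning is performed. The parent
graph is checked for cycles on every read and construction; dangling
references are reported, not fatal. Two dialects are supported: OBO 1.4
stanzas (synonym scope and source dbxref carry provenance; round-trips
exactly) and a TSV term table for curation and tests (drops axioms and
relation-type labels). The term index for tagging maps lowercased labels
(and optionally synonyms) to class ids; a surface form claimed by two
classes is excluded and reported, keeping tagging deterministic.

## Concept tagging

Matching runs on raw lowercased text, not stems — stemming would destroy
character offsets, and mined synonyms are stored with curator-supplied
surface forms precisely to bridge the stemmed mining space back to surface
text. Word boundaries are transitions to non-alphanumeric characters or
string ends ("mtx," matches "mtx"). At each position the longest matching
term wins and the scan resumes after its span (maximal munch), so
"anterior uveitis" is one match, not two. Class counting is presence-based
per post. No negation or temporality handling is attempted: every mention
counts, which matches how the frequency tables are meant to be read (topic
prevalence, not assertions about patient state) and is a known limitation.

## Statistics

**Forum comparison.** 2×2 tables (mentions vs non-mentions per forum) are
tested with Pearson's chi-square, df = 1, *without* Yates continuity
correction; the uncorrected test is the variant consistent with the
published per-class p-values this package reproduces in its acceptance
checks (e.g. the sarcoidosis table, with an expected cell near 4.8, gives
p = 0.046 only uncorrected). A zero margin raises rather than returning a
meaningless statistic.

**Sentiment.** The built-in scorer is the lexicon mean: tokenize (no
stemming, no stopword removal), average the polarities of matched tokens,
0.0 when nothing matches. The shipped lexicon is a small hand-authored
general-polarity word list (TSV, token→polarity in [−1, 1]). External
scorers are deliberately exchangeable — any callable producing scores in
[−1, 1] can replace the built-in, since lexicon tools are known to
disagree with each other substantially; the downstream analysis only
consumes scores.

**Quartile retention.** Within each forum independently, posts are sorted
by (score, post_id) and the bottom and top floor(0.25·n) retained, labelled
negative = 1 / 0. The post_id tie-break makes retention deterministic when
scores tie (common at exactly 0.0). Forums with fewer than 4 scored posts
are skipped.

**Logistic models.** Fits use statsmodels' Newton scoring (equivalently
IRLS) with an intercept, 100-iteration cap and 1e−8 tolerance. Reported
per covariate: coefficient, odds ratio, Wald CI (default 95%), Wald p.
Reported per model: log-likelihood, AIC = 2k − 2ℓ, BIC = k·ln n − 2ℓ, the
LRT p against the intercept-only model, and AUC computed as Mann–Whitney
concordance of fitted probabilities. Perfect separation (statsmodels
failure or any |coefficient| > 15) raises a named error. Univariable
screening retains candidates with single-covariate LRT p < 0.1. Backward
elimination repeatedly removes the covariate whose removal most reduces
AIC, stopping when no removal helps; BIC elimination is a configuration
switch, both criteria are recorded at every step of the trace, and forced
covariates (the first-post indicator, in the standard analysis) are exempt.
Note the statistical consequence of the criterion choice: a pure-noise
covariate survives AIC elimination with probability P(χ²₁ > 2) ≈ 0.16 but
survives BIC (n = 2000) with probability < 0.01; the test suite asserts
the sharp (≥90%) elimination property under BIC and the majority property
under AIC.

## Synthetic forum generator

The generator is the package's test bed: it emulates the statistical
features the pipeline relies on, with everything driven by one mandatory
seed (identical configurations reproduce byte-identical corpora).

* **Thread sizes** are zero-truncated negative binomial. The (r, p)
  parameters are solved numerically so that the *truncated* mean and sd
  equal the configured targets; defaults are 5.2/3.9 and 4.6/3.2 posts per
  thread for the two default forums (416 and 1488 threads), matching the
  summary statistics of the two real fora this kind of analysis is applied
  to. Sampling is inverse-CDF on (P₀, 1], so determinism needs no
  rejection loop.
* **Planted terms** (default: five clinical concepts, each with one lay
  synonym, e.g. methotrexate/mtx) are mentioned per post with per-forum
  probabilities in the 5–15% range — differing by forum, as real fora
  differ. With `misspelling_rate > 0`, a mention's surface gets one
  single-character edit (substitution or adjacent transposition) never
  touching the first character, mimicking "mxt" for "mtx". Ground truth
  records every planted mention, and the generator guarantees the emitted
  surface appears verbatim, boundary-delimited, in the post text.
* **Sentiment structure.** Each post draws from a negative, positive or
  neutral word pool (disjoint slices of the shipped lexicon; neutral posts
  contain no lexicon words and score exactly 0). The non-neutral share is
  60% in both arms. First posts draw the negative pool with higher odds
  than replies: the configured odds ratio (default 3.3) is imposed on the
  conditional negative-vs-positive odds, and the reply-arm baseline is
  calibrated per forum (using the expected first-post fraction, one per
  thread) so the overall expected negative and positive shares are 30%
  each. Two consequences make the planted value recoverable without bias:
  the 25% retained tails are then strictly inside the 30% pools, so each
  tail is a score-truncated subset of a single pool; and within a pool the
  score is independent of the first-post flag, so truncation does not
  distort the first-vs-reply composition. The fitted first-post odds ratio
  on retained posts therefore estimates the planted odds ratio directly
  (empirically: 95% CI coverage ≈ 94–98% across seeded replicate blocks).

**What the generator does not emulate:** real language (posts are shuffled
bags of phrases — adequate because the pipeline is bag-of-words), user
identity across posts (real posts from one author are correlated; neither
the real analysis nor this package models that), mixed or sarcastic
sentiment, context around mentions ("allergic to methotrexate"), or the
heavy-tailed vocabulary of real fora. Passing the synthetic recovery tests
therefore demonstrates correctness of the *machinery* — ranking, removal,
re-weighting, tagging, retention, estimation — not performance on real
forum text, where misspelling diversity, ambiguity and topic drift make
curation genuinely harder.

## Problem sizes in the shipped checks

The acceptance script and end-to-end tests use a single-forum corpus of
320–400 threads (~1600–2100 posts) for synonym recovery and 50 replicates
of a two-forum corpus of 150 + 150 threads (~1400 posts) for odds-ratio
coverage. These sizes give comfortable statistical resolution for the
properties being checked (mention counts in the hundreds; retained
regression n ≈ 700) while the whole suite stays fast.

## Known limitations

* The OBO dialect covers the tags this pipeline uses (id, name, is_a,
  synonym with scope and source, xref, relationship, equivalent_to,
  disjoint_from, comment), not the full OBO 1.4 specification, and no
  OWL/RDF serialization is provided.
* The tagger is a dictionary matcher: no statistical NER, no abbreviation
  disambiguation beyond dropping ambiguous index terms, no negation.
* Misspelling discovery relies on misspellings ranking high enough to be
  reviewed; the engine performs no edit-distance clustering.
* Sentiment is scored per post; posts mixing positive and negative
  statements about different topics collapse to one number.
* The logistic layer assumes independent posts; repeated posters violate
  this and standard errors will be somewhat optimistic on real data.
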