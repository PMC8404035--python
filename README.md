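# ontomine

Clinical ontologies speak clinician: *adalimumab*, *blurred vision*,
*methotrexate*. Patients on support forums write *humira*, *blurry*, *mtx*.
`ontomine` is a toolkit for closing that gap for inflammatory eye disease
(uveitis, scleritis, optic neuritis) and, more generally, for any domain
where an ontology must be enriched with the vocabulary patients actually
use. It is aimed at ontology engineers and clinical text-mining researchers
working with online patient-forum text.

The pipeline has three stages:

1. **Synonym mining.** Forum threads are stratified by size
   (equal-frequency binning) into train/test partitions; each training
   thread becomes a bag-of-words document (lowercased, stopword-filtered,
   Porter-stemmed). Terms are ranked by an unnormalized smoothed tf-idf,

   score(t) = max_d  tf(t, d) · [ ln((1 + N)/(1 + df(t))) + 1 ],

   and every term scoring above 1.0 goes to a curator, who accepts it as a
   synonym of an existing class (supplying the surface forms to store),
   promotes it to a new class, or rejects it. Accepted terms are removed
   from the documents, the ranking is re-run so remaining terms are
   re-weighted, and the loop repeats until a round accepts nothing.
2. **Concept tagging.** The enriched ontology becomes a dictionary tagger:
   case-insensitive, word-boundary-anchored, longest-term-first matching,
   so a synonym and its class label resolve to the same CURIE. Per-forum
   class frequencies feed 2×2 Pearson chi-square comparisons (no continuity
   correction), and the value of the mined synonyms is quantified as the
   percent increase in tagged posts, 100·(with − without)/without.
3. **Sentiment association.** Each post gets a lexicon-mean sentiment score
   in [−1, 1]; per forum, only the most negative and most positive 25% of
   posts are retained; logistic regression models the odds that a retained
   post is in the negative tail, with univariable screening (LRT p < 0.1),
   backward elimination on AIC (BIC optional), Wald CIs on odds ratios,
   likelihood-ratio global p-values and Mann–Whitney AUC. The first-post
   indicator (opening post vs reply) is a forced covariate.

A seeded synthetic-forum generator produces corpora with known ground truth
— realistic thread-size distributions, planted clinical terms with lay
synonyms and misspellings, and a configurable first-post negativity odds
ratio — so the whole pipeline is testable end to end without scraping
anything.

## Worked example

```python
from ontomine.synthetic import (GeneratorConfig, ForumConfig,
                                default_planted_terms, generate_forum,
                                generate_toy_ontology)
from ontomine.mining import (MiningConfig, ReplayCurator, CurationDecision,
                             mine_synonyms)
from ontomine.textprep import load_stopwords
from ontomine._porter import stem

terms = default_planted_terms()
cfg = GeneratorConfig(seed=7, forums={"OV": ForumConfig(400, 5.2, 3.9)},
                      planted_terms=terms)
corpus, truth = generate_forum(cfg)          # ~2000 posts, known ground truth
ontology = generate_toy_ontology(terms)      # labels only, no synonyms yet

curator = ReplayCurator({
    stem(s): CurationDecision(stem(s), "synonym_of", target_class=t.class_id,
                              surface_forms=(s,))
    for t in terms for s in t.synonyms
})
enriched, log = mine_synonyms(corpus, ontology, curator,
                              MiningConfig(seed=3), load_stopwords())
print(len(log.rounds), log.termination_reason)
for cid, cls in enriched.classes.items():
    print(cid, cls.label, [s.term for s in cls.synonyms])
```

Output:

```
2 no-accepts
OCIMIDO:00141 blurred vision ['blurry']
OCIMIDO:00213 uveitis ['iritis']
OCIMIDO:00301 methotrexate ['mtx']
OCIMIDO:00302 adalimumab ['humira']
OCIMIDO:00303 prednisolone ['steroid']
```

All five planted lay synonyms are surfaced by the tf-idf ranking in the
first round (each scores well above the 1.0 review threshold), the curator
attaches them to their classes, and the second round finds nothing new, so
the loop stops. The enriched ontology can then be written to OBO or TSV
(`ontomine.ontology.write_ontology`) and used for tagging
(`ontomine.tagging`) and the sentiment model (`ontomine.stats`).

The same operations are available from the shell:

```bash
ontomine simulate --seed 7 --out sim/
ontomine corpus summarize sim/corpus.jsonl
ontomine onto stats sim/ontology.obo
ontomine tag --corpus sim/corpus.jsonl --onto sim/ontology.obo | head
ontomine analyse --corpus sim/corpus.jsonl
```

## Layout

- `ontomine.corpus` — forum corpus model, JSONL/CSV I/O, summaries
- `ontomine.synthetic` — seeded synthetic-forum generator and toy ontologies
- `ontomine.textprep` — tokenization, stopwords, Porter stemming
- `ontomine.ontology` — ontology store, OBO/TSV dialects, term index
- `ontomine.mining` — stratified split, tf-idf ranking, curation loop
- `ontomine.tagging` — dictionary tagger, frequency tables, synonym impact
- `ontomine.stats` — chi-square, sentiment scoring, quartile retention,
  logistic modelling with screening and backward elimination
- `docs/methods.md` — models, assumptions, parameter choices, limitations
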