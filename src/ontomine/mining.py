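"""Iterative tf-idf synonym mining.

The procedure: threads are stratified by size (equal-frequency binning) into
train and test partitions; train threads become bag-of-words documents;
terms are ranked by an unnormalized smoothed tf-idf; every term scoring
above a review threshold goes to a curator, who accepts it as a synonym of
an existing class, promotes it to a new class, or rejects it; accepted terms
are removed from the documents and the ranking re-run, so remaining terms
are re-weighted; the loop stops at the first round with no accepted terms.

The tf-idf statistic per term t: idf(t) = ln((1+N)/(1+df(t))) + 1 over the N
documents; the per-document weight is raw count x idf, and the corpus score
is the maximum weight over documents (configurable to sum).  No vector
normalization is applied — the review threshold of 1.0 relies on raw scores:
a term that appears once in every document scores exactly 1.0, anything
rarer or repeated scores higher.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from ontomine.corpus import Corpus
from ontomine.ontology import Ontology, OntologyClass, SynonymAnnotation, add_synonym
from ontomine.textprep import StopwordSet, TokenStream, preprocess


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class MiningConfig:
    n_bins: int = 3
    test_fraction: float = 0.2
    score_threshold: float = 1.0
    max_rounds: int = 10
    document_unit: str = "thread"  # or "post"
    aggregate: str = "max"  # or "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise MiningError("n_bins must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise MiningError("test_fraction must be in (0, 1)")
        if self.score_threshold < 0:
            raise MiningError("score_threshold must be >= 0")
        if self.document_unit not in ("thread", "post"):
            raise MiningError("document_unit must be 'thread' or 'post'")
        if self.aggregate not in ("max", "sum"):
            raise MiningError("aggregate must be 'max' or 'sum'")


@dataclass(frozen=True)
class RankedTermList:
    """Terms with tf-idf scores, descending by (score, then term A-Z)."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        terms = [t for t, _ in self.entries]
        if len(set(terms)) != len(terms):
            raise MiningError("duplicate terms in ranked list")
        keys = [(-s, t) for t, s in self.entries]
        if keys != sorted(keys):
            raise MiningError("ranked list not sorted by (score desc, term asc)")

    def above(self, threshold: float) -> list[tuple[str, float]]:
        return [(t, s) for t, s in self.entries if s > threshold]

    def score_of(self, term: str) -> float | None:
        for t, s in self.entries:
            if t == term:
                return s
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CurationDecision:
    """One expert choice on a ranked stemmed term.

    ``surface_forms`` are the unstemmed variants (including corrected
    misspellings) to store as synonyms; the engine does no automatic
    spell-correction — misspelling consolidation is the curator's job.
    """

    term: str
    action: str  # synonym_of | new_class | reject
    target_class: str | None = None
    new_label: str | None = None
    surface_forms: tuple[str, ...] = ()
    scope: str = "unspecified"
    source: str = "mined"

    def __post_init__(self) -> None:
        if self.action not in ("synonym_of", "new_class", "reject"):
            raise MiningError(f"unknown action {self.action!r}")
        if self.action == "synonym_of" and not self.target_class:
            raise MiningError(f"decision on {self.term!r}: synonym_of needs target_class")
        if self.action == "new_class" and not self.new_label:
            raise MiningError(f"decision on {self.term!r}: new_class needs a label")


@dataclass(frozen=True)
class RoundRecord:
    round: int
    ranked_size: int
    n_reviewed: int
    n_accepted: int
    n_rejected: int
    vocabulary_size: int


@dataclass
class MiningAuditLog:
    rounds: list[RoundRecord] = field(default_factory=list)
    termination_reason: str = ""

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for rec in self.rounds:
                fh.write(json.dumps(rec.__dict__) + "\n")
            fh.write(json.dumps({"termination_reason": self.termination_reason}) + "\n")


@dataclass(frozen=True)
class ValidationReport:
    """Test-partition terms that the curation may have missed."""

    candidate_misses: tuple[str, ...]
    n_test_above_threshold: int
    n_train_above_threshold: int


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def equal_frequency_bins(sizes: Sequence[int], n_bins: int) -> list[list[int]]:
    """Indices of size-sorted items cut into n_bins contiguous groups of
    near-equal count; the remainder goes to the smallest-size bins."""
    order = sorted(range(len(sizes)), key=lambda i: (sizes[i], i))
    n = len(order)
    base, rem = divmod(n, n_bins)
    bins, start = [], 0
    for b in range(n_bins):
        width = base + (1 if b < rem else 0)
        bins.append(order[start:start + width])
        start += width
    return bins


def stratified_split(corpus: Corpus, config: MiningConfig) -> tuple[Corpus, Corpus]:
    """Split threads into train/test, stratified by thread size.

    Non-empty threads are sorted by size and cut into ``n_bins``
    equal-frequency bins; floor(test_fraction x n_threads) test threads are
    drawn without replacement, allocated to bins by largest remainder around
    each bin's floor(test_fraction x bin size) share, so every bin's test
    share is within one thread of its proportional share.  Deterministic for
    a fixed seed.
    """
    threads = corpus.nonempty_threads()
    if len(threads) < config.n_bins:
        raise MiningError(
            f"{len(threads)} non-empty threads < {config.n_bins} bins"
        )
    sizes = [t.size for t in threads]
    bins = equal_frequency_bins(sizes, config.n_bins)

    target = int(np.floor(config.test_fraction * len(threads)))
    shares = [config.test_fraction * len(b) for b in bins]
    counts = [int(np.floor(s)) for s in shares]
    if target == 0:
        warnings.warn(
            "test_fraction x n_threads < 1: falling back to one test thread per bin"
        )
        counts = [min(1, len(b)) for b in bins]
    else:
        remainders = [s - c for s, c in zip(shares, counts)]
        short = target - sum(counts)
        for b in sorted(range(len(bins)), key=lambda i: -remainders[i])[:max(short, 0)]:
            counts[b] += 1

    rng = np.random.default_rng(config.seed)
    test_idx: set[int] = set()
    for b, k in zip(bins, counts):
        k = min(k, len(b))
        if k > 0:
            test_idx.update(rng.choice(np.array(b), size=k, replace=False).tolist())

    test_ids = {threads[i].thread_id for i in test_idx}
    train = Corpus(threads=tuple(t for t in corpus.threads if t.thread_id not in test_ids))
    test = Corpus(threads=tuple(t for t in corpus.threads
                                if t.thread_id in test_ids))
    return train, test


# ---------------------------------------------------------------------------
# Documents and ranking
# ---------------------------------------------------------------------------

def build_documents(
    corpus: Corpus,
    config: MiningConfig | None = None,
    stopwords: StopwordSet | None = None,
) -> list[TokenStream]:
    """One preprocessed document per thread (posts concatenated in position
    order) or per post, depending on ``document_unit``."""
    config = config or MiningConfig()
    docs: list[TokenStream] = []
    if config.document_unit == "thread":
        for t in corpus.nonempty_threads():
            text = " ".join(p.text for p in t.posts)
            stream = preprocess(text, stopwords, source_post_id=t.thread_id)
            docs.append(stream)
    else:
        for t in corpus.nonempty_threads():
            for p in t.posts:
                docs.append(preprocess(p.text, stopwords, source_post_id=p.post_id))
    return docs


def tfidf_rank(
    documents: Sequence[TokenStream | Sequence[str]],
    config: MiningConfig | None = None,
) -> RankedTermList:
    """Rank terms by unnormalized smoothed tf-idf, aggregated over documents.

    Backed by scikit-learn's TfidfVectorizer with norm=None and
    smooth_idf=True, which implements exactly
    ``tf(t,d) * (ln((1+N)/(1+df(t))) + 1)``; the corpus-level score is the
    max (default) or sum of per-document weights.  All-empty input yields an
    empty list with a warning.
    """
    config = config or MiningConfig()
    if not documents:
        raise MiningError("tfidf_rank requires at least one document")
    token_lists = [list(d) for d in documents]
    if all(len(toks) == 0 for toks in token_lists):
        warnings.warn("all documents empty; empty ranking")
        return RankedTermList(entries=())
    vec = TfidfVectorizer(
        analyzer=lambda doc: doc,
        norm=None,
        smooth_idf=True,
        sublinear_tf=False,
        lowercase=False,
    )
    matrix = vec.fit_transform(token_lists)
    if config.aggregate == "max":
        scores = matrix.max(axis=0).toarray().ravel()
    else:
        scores = np.asarray(matrix.sum(axis=0)).ravel()
    terms = vec.get_feature_names_out()
    entries = sorted(zip(terms, scores), key=lambda ts: (-ts[1], ts[0]))
    return RankedTermList(entries=tuple((str(t), float(s)) for t, s in entries))


# ---------------------------------------------------------------------------
# Decisions
# ---------------------------------------------------------------------------

def _next_class_id(ontology: Ontology) -> str:
    """Allocate the next numeric local id in the ontology's dominant prefix."""
    prefixes: dict[str, list[int]] = {}
    width = 5
    for cid in ontology.classes:
        prefix, _, local = cid.partition(":")
        if local.isdigit():
            prefixes.setdefault(prefix, []).append(int(local))
            width = max(width, len(local))
    if not prefixes:
        return "MINED:00001"
    prefix = max(prefixes, key=lambda p: len(prefixes[p]))
    return f"{prefix}:{max(prefixes[prefix]) + 1:0{width}d}"


def apply_decisions(
    ontology: Ontology,
    documents: Sequence[TokenStream],
    decisions: Iterable[CurationDecision],
    reject_list: set[str] | None = None,
) -> tuple[Ontology, list[TokenStream], set[str]]:
    """Apply curation decisions: grow the ontology, prune the documents.

    Accepted surface forms become synonyms (or a new class's label +
    synonyms); every occurrence of each accepted stemmed term is removed
    from every document so the next ranking re-weights what remains.
    Rejected terms go on the persistent reject list and are never
    re-surfaced.  Returns the new ontology, pruned documents and the
    updated reject list.
    """
    rejects = set(reject_list) if reject_list is not None else set()
    removed_terms: set[str] = set()
    for dec in decisions:
        if dec.action == "reject":
            rejects.add(dec.term)
            continue
        surfaces = dec.surface_forms or (dec.term,)
        if dec.action == "synonym_of":
            if dec.target_class not in ontology.classes:
                raise KeyError(
                    f"decision on {dec.term!r}: unknown class {dec.target_class!r}"
                )
            for surface in surfaces:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # duplicate adds are no-ops
                    ontology = add_synonym(
                        ontology, dec.target_class, surface, dec.source, dec.scope
                    )
        else:  # new_class
            cid = _next_class_id(ontology)
            extra = tuple(s for s in surfaces if s.lower() != dec.new_label.lower())
            classes = dict(ontology.classes)
            classes[cid] = OntologyClass(
                id=cid,
                label=dec.new_label,
                synonyms=tuple(
                    SynonymAnnotation(s, dec.source, dec.scope) for s in extra
                ),
            )
            ontology = Ontology(classes=classes,
                                relation_types=dict(ontology.relation_types),
                                name=ontology.name)
        removed_terms.add(dec.term)
    if removed_terms:
        documents = [
            TokenStream(
                tokens=tuple(t for t in d.tokens if t not in removed_terms),
                source_post_id=d.source_post_id,
            )
            for d in documents
        ]
    else:
        documents = list(documents)
    return ontology, documents, rejects


def read_decisions(path: str | Path) -> dict[str, CurationDecision]:
    """Read a curation decision TSV: term, action, target_class,
    surface_forms(|), scope (header optional)."""
    decisions: dict[str, CurationDecision] = {}
    for lineno, raw in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if lineno == 1 and cols[0].lower() == "term":
            continue
        cols += [""] * (5 - len(cols))
        term, action, target, surfaces, scope = cols[:5]
        kwargs = dict(
            term=term,
            action=action,
            surface_forms=tuple(s for s in surfaces.split("|") if s),
            scope=scope or "unspecified",
        )
        if action == "synonym_of":
            kwargs["target_class"] = target
        elif action == "new_class":
            kwargs["new_label"] = target
        decisions[term] = CurationDecision(**kwargs)
    return decisions


class ReplayCurator:
    """Replays recorded expert decisions; unknown terms are rejected."""

    def __init__(self, decisions: dict[str, CurationDecision]):
        self.decisions = decisions

    @classmethod
    def from_file(cls, path: str | Path) -> "ReplayCurator":
        return cls(read_decisions(path))

    def __call__(self, review: Sequence[tuple[str, float]], round_no: int
                 ) -> list[CurationDecision]:
        out = []
        for term, _score in review:
            out.append(self.decisions.get(term, CurationDecision(term, "reject")))
        return out


Curator = Callable[[Sequence[tuple[str, float]], int], Sequence[CurationDecision]]


def mine_synonyms(
    corpus: Corpus,
    ontology: Ontology,
    curator: Curator,
    config: MiningConfig | None = None,
    stopwords: StopwordSet | None = None,
    *,
    use_split: bool = True,
    reject_list: set[str] | None = None,
) -> tuple[Ontology, MiningAuditLog]:
    """The full curate-remove-rerank loop.

    Rank the training documents, send every term scoring above the threshold
    (minus already-rejected and already-accepted terms) to the curator,
    apply the decisions, and repeat; stops at the first round accepting
    nothing, or after ``max_rounds``.  A curator failure mid-round aborts
    the loop and returns the ontology from the last completed round with the
    partial audit log.
    """
    config = config or MiningConfig()
    if use_split:
        train, _test = stratified_split(corpus, config)
    else:
        train = corpus
    documents = build_documents(train, config, stopwords)
    rejects = set(reject_list) if reject_list is not None else set()
    accepted: set[str] = set()
    log = MiningAuditLog()

    for round_no in range(1, config.max_rounds + 1):
        ranked = tfidf_rank(documents, config)
        review = [
            (t, s) for t, s in ranked.above(config.score_threshold)
            if t not in rejects and t not in accepted
        ]
        if not review:
            log.rounds.append(RoundRecord(
                round=round_no, ranked_size=len(ranked), n_reviewed=0,
                n_accepted=0, n_rejected=0,
                vocabulary_size=len(ranked),
            ))
            log.termination_reason = "no-accepts"
            return ontology, log
        try:
            decisions = list(curator(review, round_no))
        except Exception as exc:  # curator failure: flush partial log
            log.termination_reason = f"curator-error: {exc}"
            return ontology, log
        ontology, documents, rejects = apply_decisions(
            ontology, documents, decisions, rejects
        )
        n_accepts = sum(1 for d in decisions if d.action != "reject")
        accepted.update(d.term for d in decisions if d.action != "reject")
        vocab = {t for d in documents for t in d.tokens}
        log.rounds.append(RoundRecord(
            round=round_no, ranked_size=len(ranked), n_reviewed=len(review),
            n_accepted=n_accepts,
            n_rejected=sum(1 for d in decisions if d.action == "reject"),
            vocabulary_size=len(vocab),
        ))
        if n_accepts == 0:
            log.termination_reason = "no-accepts"
            return ontology, log
    log.termination_reason = "max-rounds"
    return ontology, log


def validate_split(
    train_ranked: RankedTermList,
    test_ranked: RankedTermList,
    accepted: set[str],
    threshold: float = 1.0,
) -> ValidationReport:
    """Compare train and test rankings to surface candidate missed terms:
    test-partition terms above the threshold that were neither accepted nor
    reviewable from the training partition."""
    train_terms = {t for t, _ in train_ranked.above(threshold)}
    test_terms = [t for t, _ in test_ranked.above(threshold)]
    misses = tuple(t for t in test_terms if t not in accepted and t not in train_terms)
    return ValidationReport(
        candidate_misses=misses,
        n_test_above_threshold=len(test_terms),
        n_train_above_threshold=len(train_terms),
    )
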