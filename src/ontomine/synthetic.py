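"""Synthetic forum generator.

Emits corpora with the statistical structure the pipeline assumes, so every
downstream stage (mining, tagging, sentiment modelling) is testable without
any real forum download:

* thread sizes follow a zero-truncated negative binomial whose *truncated*
  mean and sd are matched to the configured targets (defaults 5.2/3.9,
  the sizes observed on a real UK uveitis support forum);
* clinical terms with lay synonyms are planted at configurable per-post,
  per-forum mention rates, optionally misspelled by single-character edits
  that never touch the first character ("mtx" -> "mxt");
* a first-post sentiment effect: the opening post of a thread draws from a
  negative word pool with higher odds than replies, with a configurable
  odds ratio that recovery tests target.

Post text is a shuffled bag of phrases (filler words, sentiment words,
planted surfaces) — the downstream pipeline is bag-of-words, so word order
need not be realistic.  Everything is driven by one mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from ontomine.corpus import Corpus, Post, Thread
from ontomine.ontology import CURIE_RE, Ontology, OntologyClass, OntologyError
from ontomine.stats import load_lexicon

# Background filler vocabulary: everyday forum words that are neither
# stopwords, sentiment-lexicon entries, nor planted clinical surfaces.
FILLER_VOCABULARY = (
    "eye", "vision", "doctor", "appointment", "week", "month", "morning",
    "night", "clinic", "letter", "result", "question", "answer", "advice",
    "experience", "story", "update", "news", "family", "work", "school",
    "travel", "holiday", "weather", "garden", "kitchen", "window", "road",
    "train", "car", "phone", "book", "music", "film", "dinner", "lamp",
    "juice", "water", "walk", "run", "sleep", "dream", "friend", "sister",
    "brother", "mother", "father", "daughter", "son", "matron", "ward",
    "visit", "journey", "ticket", "glasses", "light", "dark", "colour",
    "shape", "sound", "voice", "hand", "arm", "leg", "head", "heart",
    "mind", "thought", "plan", "list", "note", "paper", "pen", "desk",
    "chair", "table", "door", "wall", "floor", "roof", "town", "city",
)

_FILLER_SENTENCE_BREAK = 6  # filler words per emitted sentence


@dataclass(frozen=True)
class PlantedTerm:
    """A clinical concept planted in generated text.

    ``mention_prob`` maps forum id -> per-post probability that the post
    mentions the concept; a bare float applies to every forum.  When a post
    mentions the concept, the surface form is drawn uniformly from the label
    and the synonyms.
    """

    class_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    mention_prob: float | dict[str, float] = 0.05

    def prob_for(self, forum_id: str) -> float:
        if isinstance(self.mention_prob, dict):
            return self.mention_prob.get(forum_id, 0.0)
        return self.mention_prob

    def surfaces(self) -> tuple[str, ...]:
        return (self.label,) + self.synonyms


@dataclass(frozen=True)
class ForumConfig:
    n_threads: int
    thread_size_mean: float = 5.2
    thread_size_sd: float = 3.9


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    forums: dict[str, ForumConfig] = field(
        default_factory=lambda: {"OV": ForumConfig(416, 5.2, 3.9),
                                 "UVE": ForumConfig(1488, 4.6, 3.2)}
    )
    planted_terms: tuple[PlantedTerm, ...] = ()
    misspelling_rate: float = 0.0
    first_post_negativity_or: float = 3.3
    reply_negative_prob: float | None = None  # None: calibrated per forum
    nonneutral_share: float = 0.6
    vocabulary: tuple[str, ...] = FILLER_VOCABULARY
    words_per_post: tuple[int, int] = (6, 18)  # inclusive range

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.misspelling_rate <= 1.0:
            raise ValueError("misspelling_rate must be in [0, 1]")
        if self.first_post_negativity_or <= 0:
            raise ValueError("first_post_negativity_or must be positive")
        if self.reply_negative_prob is not None and not (
            0.0 < self.reply_negative_prob < self.nonneutral_share
        ):
            raise ValueError("reply_negative_prob must lie in (0, nonneutral_share)")
        for term in self.planted_terms:
            if isinstance(term.mention_prob, dict):
                probs = term.mention_prob.values()
            else:
                probs = [term.mention_prob]
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"mention probability outside [0,1] for {term.class_id}")


def default_planted_terms() -> tuple[PlantedTerm, ...]:
    """Five clinical concepts with lay synonyms, mentioned at different rates
    in the two default forums (mirroring real cross-forum differences)."""
    return (
        PlantedTerm("OCIMIDO:00141", "blurred vision", ("blurry",),
                    {"OV": 0.06, "UVE": 0.08}),
        PlantedTerm("OCIMIDO:00213", "uveitis", ("iritis",),
                    {"OV": 0.10, "UVE": 0.12}),
        PlantedTerm("OCIMIDO:00301", "methotrexate", ("mtx",),
                    {"OV": 0.15, "UVE": 0.10}),
        PlantedTerm("OCIMIDO:00302", "adalimumab", ("humira",),
                    {"OV": 0.08, "UVE": 0.06}),
        PlantedTerm("OCIMIDO:00303", "prednisolone", ("steroid",),
                    {"OV": 0.09, "UVE": 0.07}),
    )


@dataclass
class GroundTruth:
    """What the generator planted, post by post."""

    mentions: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    sentiment_pool: dict[str, str] = field(default_factory=dict)  # post_id -> pool
    mention_counts: dict[tuple[str, str], int] = field(default_factory=dict)


def _zt_negbin_params(mean: float, sd: float) -> tuple[float, float]:
    """(r, p) of the untruncated negative binomial whose zero-truncated
    moments match the target mean and sd."""

    def moments(log_r: float, logit_p: float) -> tuple[float, float]:
        r = np.exp(log_r)
        p = 1 / (1 + np.exp(-logit_p))
        m = r * (1 - p) / p
        v = r * (1 - p) / p**2
        p0 = p**r
        mt = m / (1 - p0)
        vt = (v + m**2) / (1 - p0) - mt**2
        return mt, vt

    def objective(theta):
        mt, vt = moments(*theta)
        return [mt - mean, vt - sd**2]

    # start from the untruncated method-of-moments solution
    var = sd**2
    if var <= mean:
        raise ValueError("thread-size sd^2 must exceed the mean (overdispersion)")
    r0 = mean**2 / (var - mean)
    p0 = r0 / (r0 + mean)
    sol = optimize.root(objective, [np.log(r0), np.log(p0 / (1 - p0))], method="hybr")
    if not sol.success:
        raise ValueError(f"cannot match thread-size distribution: {sol.message}")
    r = float(np.exp(sol.x[0]))
    p = float(1 / (1 + np.exp(-sol.x[1])))
    return r, p


def _sample_zt_negbin(rng: np.random.Generator, r: float, p: float, size: int) -> np.ndarray:
    """Zero-truncated sampling by inverse CDF on (P0, 1]."""
    p0 = p**r
    u = p0 + rng.random(size) * (1 - p0)
    return sps.nbinom.ppf(u, r, p).astype(int)


def _misspell(rng: np.random.Generator, word: str) -> str:
    """Single-character edit excluding the first character."""
    if len(word) < 3:
        return word
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    i = int(rng.integers(1, len(word)))
    if rng.random() < 0.5 and i < len(word) - 1:
        # adjacent transposition ("mtx" -> "mxt")
        chars = list(word)
        chars[i], chars[i + 1] = chars[i + 1], chars[i]
        return "".join(chars)
    repl = alphabet[int(rng.integers(0, 26))]
    if repl == word[i]:
        repl = alphabet[(alphabet.index(repl) + 1) % 26]
    return word[:i] + repl + word[i + 1:]


def _neg_first_from_reply(config: GeneratorConfig, p0: float) -> float:
    """First-post negative probability implied by the configured odds ratio
    on the conditional negative-vs-positive odds."""
    s = config.nonneutral_share
    odds0 = p0 / (s - p0)
    odds1 = config.first_post_negativity_or * odds0
    return s * odds1 / (1 + odds1)


def _first_post_probs(config: GeneratorConfig, first_fraction: float
                      ) -> tuple[float, float]:
    """(p_neg_first, p_neg_reply): probability a post draws the negative pool.

    The non-neutral share is identical for first posts and replies, so the
    per-forum quartile retention recovers pool labels.  When no reply-arm
    probability is configured, it is calibrated so the *overall* expected
    negative share equals half the non-neutral share — then the retention
    boundary coincides with the pool boundary and the fitted odds ratio is
    an unbiased estimate of the planted one.
    """
    s = config.nonneutral_share
    if config.reply_negative_prob is not None:
        p0 = config.reply_negative_prob
    else:
        f = first_fraction

        def imbalance(p0_):
            return f * _neg_first_from_reply(config, p0_) + (1 - f) * p0_ - s / 2

        eps = 1e-9
        p0 = float(optimize.brentq(imbalance, eps, s - eps))
    return _neg_first_from_reply(config, p0), p0


def generate_forum(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a forum corpus and its ground truth, deterministically.

    Identical configs (including the seed) yield byte-identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = load_lexicon()
    neg_pool = lexicon.negative_pool()
    pos_pool = lexicon.positive_pool()
    s = config.nonneutral_share

    truth = GroundTruth()
    threads: list[Thread] = []
    post_counter = 0
    vocab = np.array(config.vocabulary)
    lo, hi = config.words_per_post

    for forum_id in sorted(config.forums):
        fcfg = config.forums[forum_id]
        r, p = _zt_negbin_params(fcfg.thread_size_mean, fcfg.thread_size_sd)
        sizes = _sample_zt_negbin(rng, r, p, fcfg.n_threads)
        # expected share of first posts in this forum: one per thread
        p_neg_first, p_neg_reply = _first_post_probs(
            config, 1.0 / fcfg.thread_size_mean
        )
        for t_idx, size in enumerate(sizes):
            thread_id = f"{forum_id}-t{t_idx:05d}"
            posts = []
            for position in range(int(size)):
                post_id = f"p{post_counter:07d}"
                post_counter += 1
                phrases: list[str] = []
                n_filler = int(rng.integers(lo, hi + 1))
                phrases.extend(rng.choice(vocab, size=n_filler))

                p_neg = p_neg_first if position == 0 else p_neg_reply
                u = rng.random()
                if u < p_neg:
                    pool = "negative"
                    words = neg_pool
                elif u < s:
                    pool = "positive"
                    words = pos_pool
                else:
                    pool = "neutral"
                    words = None
                if words is not None:
                    k = int(rng.integers(2, 6))
                    phrases.extend(rng.choice(np.array(words), size=k))
                truth.sentiment_pool[post_id] = pool

                mentioned: list[tuple[str, str]] = []
                for term in config.planted_terms:
                    if rng.random() < term.prob_for(forum_id):
                        surfaces = term.surfaces()
                        surface = surfaces[int(rng.integers(0, len(surfaces)))]
                        if config.misspelling_rate > 0 and rng.random() < config.misspelling_rate:
                            words_ = surface.split()
                            j = int(rng.integers(0, len(words_)))
                            words_[j] = _misspell(rng, words_[j])
                            surface = " ".join(words_)
                        phrases.append(surface)
                        mentioned.append((term.class_id, surface))
                if mentioned:
                    truth.mentions[post_id] = mentioned
                    for class_id in {c for c, _ in mentioned}:
                        key = (forum_id, class_id)
                        truth.mention_counts[key] = truth.mention_counts.get(key, 0) + 1

                order = rng.permutation(len(phrases))
                shuffled = [str(phrases[i]) for i in order]
                # group into short filler sentences for a vaguely post-like shape
                sentences = [
                    " ".join(shuffled[i:i + _FILLER_SENTENCE_BREAK])
                    for i in range(0, len(shuffled), _FILLER_SENTENCE_BREAK)
                ]
                text = ". ".join(sentences) + "."
                posts.append(Post(post_id=post_id, thread_id=thread_id,
                                  forum_id=forum_id, position=position, text=text))
            threads.append(Thread(thread_id=thread_id, forum_id=forum_id,
                                  posts=tuple(posts)))
    return Corpus(threads=tuple(threads)), truth


def generate_toy_ontology(planted_terms: tuple[PlantedTerm, ...],
                          name: str = "toy") -> Ontology:
    """One class per planted term: label only, no synonyms — the synonyms are
    exactly what the mining loop must recover."""
    classes: dict[str, OntologyClass] = {}
    for term in planted_terms:
        if not CURIE_RE.match(term.class_id):
            raise OntologyError(f"invalid CURIE {term.class_id!r}")
        if term.class_id in classes:
            raise OntologyError(f"duplicate class id {term.class_id!r}")
        classes[term.class_id] = OntologyClass(id=term.class_id, label=term.label)
    return Ontology(classes=classes, name=name)
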