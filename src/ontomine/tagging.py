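"""Dictionary concept tagging.

Posts are matched against the term index (labels plus mined synonyms) on
the raw lowercased text: case-insensitive, word-boundary-anchored, longest
term first, greedily left to right with non-overlapping spans — so
"anterior uveitis" claims its whole span before "uveitis" can.  Matching
happens on surface text, not stems, which keeps character offsets
meaningful; mined synonyms are stored with their curator-supplied surface
forms for exactly this reason.

No context disambiguation (negation, temporality) is attempted: every
mention counts, and a class counts once per post however often it recurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from ontomine.corpus import Corpus
from ontomine.ontology import TermIndex


class TaggingError(ValueError):
    pass


@dataclass(frozen=True)
class TagResult:
    """Matches for one post: (class id, start, end, surface), 0-based
    half-open character offsets, non-overlapping."""

    post_id: str
    matches: tuple[tuple[str, int, int, str], ...]

    @property
    def class_ids(self) -> frozenset[str]:
        return frozenset(m[0] for m in self.matches)


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def _boundary_ok(text: str, start: int, end: int) -> bool:
    before_ok = start == 0 or not _is_word_char(text[start - 1])
    after_ok = end == len(text) or not _is_word_char(text[end])
    return before_ok and after_ok


def tag_post(text: str, index: TermIndex, *, post_id: str = "") -> TagResult:
    """Tag one post against the index.

    At each position, the longest boundary-anchored term starting there
    wins; the scan then resumes after its span (maximal munch).
    """
    lowered = text.lower()
    terms = index.terms_longest_first
    matches: list[tuple[str, int, int, str]] = []
    pos = 0
    n = len(lowered)
    while pos < n:
        if not _is_word_char(lowered[pos]) or (pos > 0 and _is_word_char(lowered[pos - 1])):
            pos += 1
            continue
        hit = None
        for term in terms:  # longest first
            end = pos + len(term)
            if lowered.startswith(term, pos) and _boundary_ok(lowered, pos, end):
                hit = (index.term_to_class[term], pos, end, text[pos:end])
                break
        if hit is None:
            pos += 1
        else:
            matches.append(hit)
            pos = hit[2]
    return TagResult(post_id=post_id, matches=tuple(matches))


def tag_corpus(corpus: Corpus, index: TermIndex) -> list[TagResult]:
    """One TagResult per post, in corpus order."""
    return [
        tag_post(p.text, index, post_id=p.post_id)
        for t in corpus.threads
        for p in t.posts
    ]


@dataclass(frozen=True)
class FrequencyTable:
    """Per class x forum: number (and percent) of posts with >= 1 mention."""

    table: pd.DataFrame  # columns: class_id, forum_id, n_posts_mentioning, percent
    forum_totals: dict[str, int]

    def count(self, class_id: str, forum_id: str) -> int:
        sel = self.table[
            (self.table.class_id == class_id) & (self.table.forum_id == forum_id)
        ]
        return int(sel.n_posts_mentioning.iloc[0]) if len(sel) else 0

    def percent(self, class_id: str, forum_id: str) -> float:
        sel = self.table[
            (self.table.class_id == class_id) & (self.table.forum_id == forum_id)
        ]
        return float(sel.percent.iloc[0]) if len(sel) else 0.0


def frequency_table(tags: list[TagResult], corpus: Corpus) -> FrequencyTable:
    """Post-level mention frequencies per class and forum.

    Counting is presence-based: repeat mentions within a post do not
    inflate the count.  Forums with zero posts are omitted with a warning.
    """
    post_forum = {p.post_id: p.forum_id for t in corpus.threads for p in t.posts}
    unknown = [tr.post_id for tr in tags if tr.post_id not in post_forum]
    if unknown:
        raise TaggingError(f"tags reference unknown post(s): {unknown[:3]}")
    totals: dict[str, int] = {}
    for t in corpus.threads:
        totals[t.forum_id] = totals.get(t.forum_id, 0) + t.size
    for fid, total in list(totals.items()):
        if total == 0:
            warnings.warn(f"forum {fid!r} has zero posts; omitted")
            del totals[fid]

    counts: dict[tuple[str, str], int] = {}
    for tr in tags:
        fid = post_forum[tr.post_id]
        if fid not in totals:
            continue
        for cid in tr.class_ids:
            counts[(cid, fid)] = counts.get((cid, fid), 0) + 1
    rows = [
        {
            "class_id": cid,
            "forum_id": fid,
            "n_posts_mentioning": n,
            "percent": 100.0 * n / totals[fid],
        }
        for (cid, fid), n in sorted(counts.items())
    ]
    return FrequencyTable(
        table=pd.DataFrame(rows, columns=["class_id", "forum_id",
                                          "n_posts_mentioning", "percent"]),
        forum_totals=totals,
    )


def synonym_impact(count_labels_only: int, count_with_synonyms: int) -> float | None:
    """Percent increase in tagged posts attributable to synonyms.

    ``100 * (with - without) / without``; reports round this to the nearest
    integer percent.  Returns None ("new coverage") when the labels-only
    count is zero.  The synonym index is a superset of the labels-only
    index, so a with-synonyms count below the labels-only count signals an
    upstream bug and raises.
    """
    if count_labels_only < 0 or count_with_synonyms < 0:
        raise TaggingError("counts must be non-negative")
    if count_with_synonyms < count_labels_only:
        raise TaggingError(
            "with-synonyms count below labels-only count violates the superset property"
        )
    if count_labels_only == 0:
        return None
    return 100.0 * (count_with_synonyms - count_labels_only) / count_labels_only
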