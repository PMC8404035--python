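"""Forum-corpus data model, JSONL/CSV I/O and descriptive summaries.

A corpus is a flat collection of posts grouped into threads within forums.
The first post of a thread (position 0) is distinguished from replies —
downstream sentiment models use that indicator.  JSON Lines (one post per
record) is the canonical on-disk form; CSV is a convenience dialect with
quoted UTF-8 text, since post text routinely contains commas and newlines.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_FIELDS = ("post_id", "thread_id", "forum_id", "position", "text")


class CorpusError(ValueError):
    """Malformed or inconsistent corpus data."""


@dataclass(frozen=True)
class Post:
    post_id: str
    thread_id: str
    forum_id: str
    position: int
    text: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise CorpusError(f"post {self.post_id!r}: negative position")
        if self.text is None:
            raise CorpusError(f"post {self.post_id!r}: text absent")

    @property
    def is_first(self) -> bool:
        return self.position == 0


@dataclass(frozen=True)
class Thread:
    thread_id: str
    forum_id: str
    posts: tuple[Post, ...]

    def __post_init__(self) -> None:
        positions = [p.position for p in self.posts]
        if positions != sorted(positions):
            raise CorpusError(f"thread {self.thread_id!r}: posts not sorted by position")
        if sum(1 for p in self.posts if p.position == 0) > 1:
            raise CorpusError(f"thread {self.thread_id!r}: multiple first posts")
        for p in self.posts:
            if p.forum_id != self.forum_id:
                raise CorpusError(
                    f"post {p.post_id!r}: forum {p.forum_id!r} != thread forum {self.forum_id!r}"
                )

    @property
    def size(self) -> int:
        return len(self.posts)


@dataclass(frozen=True)
class Corpus:
    threads: tuple[Thread, ...]

    def __post_init__(self) -> None:
        ids = [t.thread_id for t in self.threads]
        if len(set(ids)) != len(ids):
            raise CorpusError("duplicate thread_id in corpus")

    @property
    def forum_ids(self) -> frozenset[str]:
        return frozenset(t.forum_id for t in self.threads)

    @property
    def posts(self) -> list[Post]:
        return [p for t in self.threads for p in t.posts]

    @property
    def n_posts(self) -> int:
        return sum(t.size for t in self.threads)

    def nonempty_threads(self) -> list[Thread]:
        """Threads carrying at least one post (empty threads are retained on
        read but excluded from binning, mining and summaries)."""
        return [t for t in self.threads if t.size > 0]


@dataclass(frozen=True)
class ForumSummary:
    forum_id: str
    n_posts: int
    n_threads: int
    mean_posts_per_thread: float
    sd_posts_per_thread: float
    min_thread_size: int
    max_thread_size: int


@dataclass(frozen=True)
class CorpusSummary:
    forums: dict[str, ForumSummary] = field(default_factory=dict)

    @property
    def n_posts(self) -> int:
        return sum(f.n_posts for f in self.forums.values())

    @property
    def n_threads(self) -> int:
        return sum(f.n_threads for f in self.forums.values())

    def to_text(self) -> str:
        lines = []
        for fid in sorted(self.forums):
            f = self.forums[fid]
            lines.append(
                f"{fid}: {f.n_posts} posts in {f.n_threads} threads, "
                f"mean {f.mean_posts_per_thread:.1f} (sd {f.sd_posts_per_thread:.1f}) "
                f"posts/thread, range {f.min_thread_size} to {f.max_thread_size}"
            )
        lines.append(f"TOTAL: {self.n_posts} posts in {self.n_threads} threads")
        return "\n".join(lines)


def _assemble(records: list[dict]) -> Corpus:
    seen_posts: set[str] = set()
    by_thread: dict[str, list[Post]] = {}
    thread_forum: dict[str, str] = {}
    for i, rec in enumerate(records, start=1):
        missing = [f for f in _FIELDS if f not in rec or rec[f] is None]
        if missing:
            raise CorpusError(f"record {i}: missing field(s) {missing}")
        try:
            position = int(rec["position"])
        except (TypeError, ValueError) as exc:
            raise CorpusError(f"record {i}: position not an integer") from exc
        post = Post(
            post_id=str(rec["post_id"]),
            thread_id=str(rec["thread_id"]),
            forum_id=str(rec["forum_id"]),
            position=position,
            text=str(rec["text"]),
        )
        if post.post_id in seen_posts:
            raise CorpusError(f"record {i}: duplicate post_id {post.post_id!r}")
        seen_posts.add(post.post_id)
        prev = thread_forum.setdefault(post.thread_id, post.forum_id)
        if prev != post.forum_id:
            raise CorpusError(
                f"thread {post.thread_id!r}: inconsistent forum ids {prev!r}/{post.forum_id!r}"
            )
        by_thread.setdefault(post.thread_id, []).append(post)
    threads = tuple(
        Thread(
            thread_id=tid,
            forum_id=thread_forum[tid],
            posts=tuple(sorted(posts, key=lambda p: p.position)),
        )
        for tid, posts in by_thread.items()
    )
    return Corpus(threads=threads)


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL (canonical) or CSV.

    The format is inferred from the suffix when not given.  Malformed
    records raise :class:`CorpusError` naming the offending line.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    records: list[dict] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"line {lineno}: invalid JSON: {exc}") from exc
    elif fmt == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            records.extend(csv.DictReader(fh))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return _assemble(records)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus; ``read_corpus`` on the result reproduces it field-for-field."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    rows = [
        {
            "post_id": p.post_id,
            "thread_id": p.thread_id,
            "forum_id": p.forum_id,
            "position": p.position,
            "text": p.text,
        }
        for t in corpus.threads
        for p in t.posts
    ]
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS, quoting=csv.QUOTE_ALL)
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def summarize_corpus(corpus: Corpus) -> CorpusSummary:
    """Per-forum post/thread counts and posts-per-thread mean and sd.

    The sd uses the sample (n-1) denominator.  Forums whose every thread is
    empty are omitted with a warning.
    """
    by_forum: dict[str, list[int]] = {}
    for t in corpus.threads:
        by_forum.setdefault(t.forum_id, [])
        if t.size > 0:
            by_forum[t.forum_id].append(t.size)
    forums: dict[str, ForumSummary] = {}
    for fid in sorted(by_forum):
        sizes = by_forum[fid]
        if not sizes:
            warnings.warn(f"forum {fid!r} has no non-empty threads; omitted from summary")
            continue
        arr = np.asarray(sizes, dtype=float)
        forums[fid] = ForumSummary(
            forum_id=fid,
            n_posts=int(arr.sum()),
            n_threads=len(sizes),
            mean_posts_per_thread=float(arr.mean()),
            sd_posts_per_thread=float(arr.std(ddof=1)) if len(sizes) > 1 else 0.0,
            min_thread_size=int(arr.min()),
            max_thread_size=int(arr.max()),
        )
    return CorpusSummary(forums=forums)
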