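"""Text normalisation for forum posts.

Posts are reduced to the representation the mining stage works in: lowercase,
tokenized on non-alphanumeric boundaries, stopwords dropped, and each
remaining token Porter-stemmed (so "pained", "painful" and "pains" all
collapse to "pain").  Numerals are kept — disease-grading terms such as
"grade 1" are clinically meaningful.

The default stopword list is a standard English list extended with forum
pleasantries ("thanks", "xx", ...) and ships as an editable plain-text file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ontomine._porter import stem as porter_stem

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class TokenStream:
    """Ordered lowercase stemmed tokens derived from one source text."""

    tokens: tuple[str, ...]
    source_post_id: str | None = None

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class StopwordSet:
    """A set of lowercase words removed before stemming."""

    words: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = {w for w in self.words if w != w.lower()}
        if bad:
            raise ValueError(f"stopwords must be lowercase: {sorted(bad)[:5]}")

    def __contains__(self, word: str) -> bool:
        return word in self.words


def load_stopwords(path: str | Path | None = None) -> StopwordSet:
    """Load a stopword file (one word per line, '#' comments).

    With no path, the packaged default list is used.
    """
    if path is None:
        text = (resources.files("ontomine") / "data" / "stopwords.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return StopwordSet(frozenset(words))


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any character outside [a-z0-9].

    Hyphenated terms split into their parts; punctuation disappears.  Used
    both here and by the sentiment scorer (which skips stopword removal and
    stemming).
    """
    return _TOKEN_RE.findall(text.lower())


def preprocess(
    text: str,
    stopwords: StopwordSet | None = None,
    *,
    source_post_id: str | None = None,
) -> TokenStream:
    """Normalise raw text into a :class:`TokenStream`.

    Tokenization, lowercasing, stopword removal and Porter stemming, in that
    order.  Total: empty text yields an empty stream.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    tokens = tuple(
        porter_stem(tok) for tok in tokenize(text) if tok not in stopwords
    )
    return TokenStream(tokens=tokens, source_post_id=source_post_id)
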