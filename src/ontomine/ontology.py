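"""Ontology store: CURIE-identified classes with labels, provenance-tagged
synonyms, cross-references to external terminologies (SNOMED-CT, ICD-10,
Read, DOID, HPO, ORDO, PATO, UBERON, ...), a subsumption hierarchy and
constructed relationships (part-of, adjacent-to, investigated-by, ...).

Two flat-file dialects are supported: OBO 1.4 stanzas (synonym scope and a
source dbxref carry provenance) and a TSV term table for curation and tests.
Equivalence/disjointness axioms are stored as annotation pairs and checked
structurally — a class cannot be both equivalent and disjoint to the same
target — but no description-logic reasoning is performed.
"""

from __future__ import annotations

import graphlib
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

CURIE_RE = re.compile(r"^[A-Za-z][\w.-]*:\S+$")

SYNONYM_SCOPES = ("exact", "narrow", "broad", "related", "unspecified")


class OntologyError(ValueError):
    """Structural problem in ontology data."""


class CycleError(OntologyError):
    """Cycle in the parent (is_a) graph."""


@dataclass(frozen=True)
class SynonymAnnotation:
    term: str
    source: str = "unknown"
    scope: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.term:
            raise OntologyError("synonym term must be non-empty")
        if not self.source:
            raise OntologyError("synonym source must be non-empty")
        if self.scope not in SYNONYM_SCOPES:
            raise OntologyError(f"unknown synonym scope {self.scope!r}")


@dataclass(frozen=True)
class OntologyClass:
    id: str
    label: str
    synonyms: tuple[SynonymAnnotation, ...] = ()
    xrefs: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    relationships: tuple[tuple[str, str], ...] = ()  # (relation CURIE, target CURIE)
    axioms: tuple[tuple[str, str], ...] = ()  # (axiom type, target CURIE)
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.id):
            raise OntologyError(f"invalid CURIE {self.id!r}")
        if not self.label:
            raise OntologyError(f"class {self.id}: empty label")
        for syn in self.synonyms:
            if syn.term.lower() == self.label.lower():
                raise OntologyError(
                    f"class {self.id}: synonym {syn.term!r} duplicates the label"
                )
        eq = {t for kind, t in self.axioms if kind == "equivalent_to"}
        dj = {t for kind, t in self.axioms if kind == "disjoint_from"}
        both = eq & dj
        if both:
            raise OntologyError(
                f"class {self.id}: equivalent and disjoint to the same class(es) {sorted(both)}"
            )


@dataclass
class Ontology:
    classes: dict[str, OntologyClass] = field(default_factory=dict)
    relation_types: dict[str, str] = field(default_factory=dict)  # id -> label
    name: str = "ontology"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        sorter = graphlib.TopologicalSorter(
            {cid: [p for p in cls.parents if p in self.classes]
             for cid, cls in self.classes.items()}
        )
        try:
            sorter.prepare()
        except graphlib.CycleError as exc:
            raise CycleError(f"cycle in parent graph: {exc.args[1]}") from exc

    def dangling_references(self) -> list[tuple[str, str, str]]:
        """(class id, kind, target) triples whose target is not a known class."""
        out = []
        for cid, cls in sorted(self.classes.items()):
            for p in cls.parents:
                if p not in self.classes:
                    out.append((cid, "parent", p))
            for rel, target in cls.relationships:
                if target not in self.classes:
                    out.append((cid, rel, target))
            for kind, target in cls.axioms:
                if target not in self.classes:
                    out.append((cid, kind, target))
        return out


@dataclass(frozen=True)
class OntologyStats:
    n_classes: int
    n_synonyms: int
    n_xrefs: int
    n_relationships: int
    n_annotations: int
    synonyms_by_source: dict[str, int] = field(default_factory=dict)


def ontology_stats(ontology: Ontology) -> OntologyStats:
    """Exact counts by category.

    Relationships count parent (is_a) links, constructed relationships and
    axiom pairs; annotations count synonyms, cross-references and comments.
    """
    n_syn = n_xref = n_rel = n_comment = 0
    by_source: dict[str, int] = {}
    for cls in ontology.classes.values():
        n_syn += len(cls.synonyms)
        n_xref += len(cls.xrefs)
        n_rel += len(cls.parents) + len(cls.relationships) + len(cls.axioms)
        n_comment += len(cls.comments)
        for syn in cls.synonyms:
            by_source[syn.source] = by_source.get(syn.source, 0) + 1
    return OntologyStats(
        n_classes=len(ontology.classes),
        n_synonyms=n_syn,
        n_xrefs=n_xref,
        n_relationships=n_rel,
        n_annotations=n_syn + n_xref + n_comment,
        synonyms_by_source=by_source,
    )


def add_synonym(
    ontology: Ontology,
    class_id: str,
    term: str,
    source: str,
    scope: str = "unspecified",
) -> Ontology:
    """Return the ontology with *term* appended as a synonym of *class_id*.

    Duplicate (class, term) pairs are no-ops with a warning; unknown class
    ids raise :class:`KeyError`.
    """
    if class_id not in ontology.classes:
        raise KeyError(f"unknown class id {class_id!r}")
    if not term:
        raise OntologyError("synonym term must be non-empty")
    cls = ontology.classes[class_id]
    if any(s.term.lower() == term.lower() for s in cls.synonyms):
        warnings.warn(f"{class_id}: synonym {term!r} already present; ignored")
        return ontology
    new_cls = replace(
        cls, synonyms=cls.synonyms + (SynonymAnnotation(term, source, scope),)
    )
    classes = dict(ontology.classes)
    classes[class_id] = new_cls
    return Ontology(classes=classes, relation_types=dict(ontology.relation_types),
                    name=ontology.name)


# ---------------------------------------------------------------------------
# Term index for the dictionary tagger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermIndex:
    """Case-insensitive surface term -> class id map, longest terms first.

    Terms whose surface form maps to more than one class are excluded and
    listed in :attr:`ambiguous`.
    """

    term_to_class: dict[str, str]
    ambiguous: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def terms_longest_first(self) -> tuple[str, ...]:
        return tuple(sorted(self.term_to_class, key=lambda t: (-len(t), t)))

    def __len__(self) -> int:
        return len(self.term_to_class)


def build_term_index(ontology: Ontology, include_synonyms: bool = True) -> TermIndex:
    """Build the tagging dictionary: labels always, synonyms when asked.

    Lowercased surface forms; multiword terms preserved; a term claimed by
    two classes is dropped with a logged ambiguity entry so tagging stays
    deterministic.
    """
    claims: dict[str, set[str]] = {}
    for cid, cls in ontology.classes.items():
        claims.setdefault(cls.label.lower(), set()).add(cid)
        if include_synonyms:
            for syn in cls.synonyms:
                claims.setdefault(syn.term.lower(), set()).add(cid)
    term_to_class: dict[str, str] = {}
    ambiguous: dict[str, tuple[str, ...]] = {}
    for term, cids in claims.items():
        if len(cids) == 1:
            term_to_class[term] = next(iter(cids))
        else:
            ambiguous[term] = tuple(sorted(cids))
            warnings.warn(
                f"term {term!r} is ambiguous between {sorted(cids)}; dropped from index"
            )
    return TermIndex(term_to_class=term_to_class, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# OBO dialect
# ---------------------------------------------------------------------------

_OBO_SCOPE = {"exact": "EXACT", "narrow": "NARROW", "broad": "BROAD", "related": "RELATED"}
_OBO_SCOPE_INV = {v: k for k, v in _OBO_SCOPE.items()}

_SYN_LINE_RE = re.compile(
    r'^"(?P<term>(?:[^"\\]|\\.)*)"\s*(?P<scope>EXACT|NARROW|BROAD|RELATED)?\s*'
    r"(?:\[(?P<refs>[^\]]*)\])?\s*$"
)


def _parse_synonym_line(value: str, class_id: str) -> SynonymAnnotation:
    m = _SYN_LINE_RE.match(value.strip())
    if not m:
        raise OntologyError(f"class {class_id}: malformed synonym line {value!r}")
    term = m.group("term").replace('\\"', '"')
    scope = _OBO_SCOPE_INV.get(m.group("scope") or "", "unspecified")
    refs = (m.group("refs") or "").strip()
    source = refs.split(",")[0].strip() if refs else "unknown"
    return SynonymAnnotation(term=term, source=source or "unknown", scope=scope)


def _read_obo(path: Path) -> Ontology:
    classes: dict[str, OntologyClass] = {}
    relation_types: dict[str, str] = {}
    name = path.stem
    stanza: list[tuple[str, str]] | None = None
    kind = None

    def flush() -> None:
        nonlocal stanza
        if stanza is None:
            return
        fields = stanza
        stanza = None
        tags: dict[str, list[str]] = {}
        for k, v in fields:
            tags.setdefault(k, []).append(v)
        if kind == "Typedef":
            tid = tags.get("id", [None])[0]
            if tid:
                relation_types[tid] = tags.get("name", [tid])[0]
            return
        cid = tags.get("id", [None])[0]
        if cid is None:
            raise OntologyError("Term stanza without id")
        if cid in classes:
            raise OntologyError(f"duplicate class id {cid!r}")
        rels, axioms = [], []
        for v in tags.get("relationship", []):
            parts = v.split()
            if len(parts) < 2:
                raise OntologyError(f"class {cid}: malformed relationship {v!r}")
            rels.append((parts[0], parts[1]))
        for ax_kind in ("equivalent_to", "disjoint_from"):
            for v in tags.get(ax_kind, []):
                axioms.append((ax_kind, v.split()[0]))
        classes[cid] = OntologyClass(
            id=cid,
            label=tags.get("name", [""])[0],
            synonyms=tuple(_parse_synonym_line(v, cid) for v in tags.get("synonym", [])),
            xrefs=tuple(v.split()[0] for v in tags.get("xref", [])),
            parents=tuple(v.split()[0] for v in tags.get("is_a", [])),
            relationships=tuple(rels),
            axioms=tuple(axioms),
            comments=tuple(tags.get("comment", [])),
        )

    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("!", 1)[0].rstrip("\n").strip()
            if not line:
                continue
            if line.startswith("["):
                flush()
                kind = line.strip("[]")
                stanza = [] if kind in ("Term", "Typedef") else None
                continue
            if stanza is None:
                if line.startswith("ontology:"):
                    name = line.split(":", 1)[1].strip()
                continue
            if ":" not in line:
                raise OntologyError(f"malformed OBO line {raw.rstrip()!r}")
            k, v = line.split(":", 1)
            stanza.append((k.strip(), v.strip()))
    flush()
    return Ontology(classes=classes, relation_types=relation_types, name=name)


def _write_obo(ontology: Ontology, path: Path) -> None:
    lines = ["format-version: 1.4", f"ontology: {ontology.name}", ""]
    for tid in sorted(ontology.relation_types):
        lines += ["[Typedef]", f"id: {tid}", f"name: {ontology.relation_types[tid]}", ""]
    for cid in sorted(ontology.classes):
        cls = ontology.classes[cid]
        lines += ["[Term]", f"id: {cls.id}", f"name: {cls.label}"]
        for syn in cls.synonyms:
            term = syn.term.replace('"', '\\"')
            scope = _OBO_SCOPE.get(syn.scope)
            src = "" if syn.source == "unknown" else syn.source
            parts = [f'"{term}"'] + ([scope] if scope else []) + [f"[{src}]"]
            lines.append("synonym: " + " ".join(parts))
        for xref in cls.xrefs:
            lines.append(f"xref: {xref}")
        for parent in cls.parents:
            lines.append(f"is_a: {parent}")
        for rel, target in cls.relationships:
            lines.append(f"relationship: {rel} {target}")
        for kind, target in cls.axioms:
            lines.append(f"{kind}: {target}")
        for comment in cls.comments:
            lines.append(f"comment: {comment}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("id", "label", "parents", "synonyms", "xrefs", "relationships", "comments")


def _encode_syn(syn: SynonymAnnotation) -> str:
    if syn.source == "unknown" and syn.scope == "unspecified":
        return syn.term
    return f"{syn.term}@{syn.source}@{syn.scope}"


def _decode_syn(text: str) -> SynonymAnnotation:
    parts = text.split("@")
    if len(parts) == 1:
        return SynonymAnnotation(term=parts[0])
    if len(parts) == 2:
        return SynonymAnnotation(term=parts[0], source=parts[1] or "unknown")
    return SynonymAnnotation(
        term=parts[0], source=parts[1] or "unknown", scope=parts[2] or "unspecified"
    )


def _read_tsv(path: Path) -> Ontology:
    classes: dict[str, OntologyClass] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for col in ("id", "label"):
            if col not in idx:
                raise OntologyError(f"TSV missing required column {col!r}")

        def cell(row: list[str], col: str) -> str:
            i = idx.get(col)
            return row[i] if i is not None and i < len(row) else ""

        def split(value: str) -> list[str]:
            return [v for v in value.split("|") if v]

        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            row = raw.rstrip("\n").split("\t")
            cid = cell(row, "id")
            if cid in classes:
                raise OntologyError(f"line {lineno}: duplicate class id {cid!r}")
            rels = []
            for item in split(cell(row, "relationships")):
                rel, _, target = item.partition(" ")
                if not target:
                    raise OntologyError(f"line {lineno}: malformed relationship {item!r}")
                rels.append((rel, target))
            classes[cid] = OntologyClass(
                id=cid,
                label=cell(row, "label"),
                parents=tuple(split(cell(row, "parents"))),
                synonyms=tuple(_decode_syn(s) for s in split(cell(row, "synonyms"))),
                xrefs=tuple(split(cell(row, "xrefs"))),
                relationships=tuple(rels),
                comments=tuple(split(cell(row, "comments"))),
            )
    return Ontology(classes=classes, name=path.stem)


def _write_tsv(ontology: Ontology, path: Path) -> None:
    lines = ["\t".join(_TSV_COLUMNS)]
    for cid in sorted(ontology.classes):
        cls = ontology.classes[cid]
        lines.append("\t".join([
            cls.id,
            cls.label,
            "|".join(cls.parents),
            "|".join(_encode_syn(s) for s in cls.synonyms),
            "|".join(cls.xrefs),
            "|".join(f"{rel} {target}" for rel, target in cls.relationships),
            "|".join(cls.comments),
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ontology(path: str | Path, format: str | None = None) -> Ontology:
    """Read an ontology from an OBO flat file or the TSV term table.

    Dangling references are collected via :meth:`Ontology.dangling_references`
    rather than raised; duplicate ids and parent cycles are fatal.
    """
    path = Path(path)
    fmt = format or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "obo")
    if fmt == "obo":
        return _read_obo(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown ontology format {fmt!r}")


def write_ontology(ontology: Ontology, path: str | Path, format: str | None = None) -> None:
    """Write the ontology; stanzas/rows are emitted sorted by class id, and
    ``read_ontology`` on the result reproduces the input (TSV drops axiom
    pairs and typedef labels, which only the OBO dialect carries)."""
    path = Path(path)
    fmt = format or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "obo")
    if fmt == "obo":
        _write_obo(ontology, path)
    elif fmt == "tsv":
        _write_tsv(ontology, path)
    else:
        raise ValueError(f"unknown ontology format {fmt!r}")
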