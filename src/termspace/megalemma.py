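"""Cross-lingual lexical normalization: megalemmas and megatokens.

A *megalemma* is a cluster of surface word forms — across inflections and
across languages — treated as one canonical lexical unit with an uppercase
label: the VIRUS megalemma holds the English "virus"/"viruses" and the
Russian "virusnye"/"virusologia".  A *megatoken* is a canonically ordered
tuple of megalemma labels standing for a multiword collocation, so
"genetic disease" and its Russian counterpart both normalize to the single
megatoken GEN + DISEASE.

Canonical megatoken order is case-insensitive lexicographic (storage);
display is root-first, matching how such units are conventionally printed
(PREDICT + MODEL, GEN + DISEASE), with the non-root labels following in
canonical order.

Dictionary growth: a new word is proposed for merging into an existing
megalemma when its embedding is close to the megalemma's member centroid
AND it shares the megalemma-label contexts (Jaccard overlap) seen in
parallel texts.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import Corpus, Document, tokenize

__all__ = [
    "Megalemma",
    "Megatoken",
    "MegalemmaDict",
    "MegatokenSequence",
    "MergeProposal",
    "ContextSets",
    "MegatokenEncoder",
    "lookup",
    "megatoken_of",
    "text_to_megatokens",
    "propose_merge",
    "build_context_sets",
    "load_embeddings",
]

#: Labels rendered first in megatoken display when present.
DEFAULT_ROOT_LABELS = ("PREDICT", "PERSONALIZE", "PROGNOSIS", "PREVENT", "GEN")

DEFAULT_VECTOR_THRESHOLD = 0.7
DEFAULT_CONTEXT_THRESHOLD = 0.3


def _norm(form: str) -> str:
    return unicodedata.normalize("NFC", form).lower()


@dataclass(frozen=True)
class Megalemma:
    """One cross-lingual word-form cluster."""

    label: str
    forms: frozenset[tuple[str, str]]  # (surface form, language tag)

    def __post_init__(self) -> None:
        if not self.forms:
            raise ValueError(f"megalemma {self.label!r} has no forms")

    def surfaces(self, language: str | None = None) -> set[str]:
        return {s for s, lang in self.forms if language is None or lang == language}


@dataclass(frozen=True)
class Megatoken:
    """Canonically ordered tuple of megalemma labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("megatoken needs at least one label")
        object.__setattr__(
            self, "labels", tuple(sorted(self.labels, key=str.lower))
        )

    def display(self, root_labels: Iterable[str] = DEFAULT_ROOT_LABELS) -> str:
        """Root-first rendering, e.g. ``GEN + DISEASE``; derived, never stored."""
        roots = set(root_labels)
        ordered = list(self.labels)
        for lab in ordered:
            if lab in roots:
                ordered.remove(lab)
                ordered.insert(0, lab)
                break
        return " + ".join(ordered)

    def __str__(self) -> str:  # canonical order
        return " + ".join(self.labels)


class MegalemmaDict:
    """Label -> megalemma mapping with a consistent (surface, language)
    reverse index, plus the set of dictionary-known megatokens.

    A surface form may belong to only one megalemma within a language;
    identical spellings in different languages may map to different
    megalemmas.
    """

    def __init__(self) -> None:
        self.entries: dict[str, Megalemma] = {}
        self.megatokens: set[tuple[str, ...]] = set()
        self._reverse: dict[tuple[str, str], str] = {}

    def add(self, label: str, forms: Iterable[tuple[str, str]]) -> None:
        label = label.upper()
        new_forms = {(_norm(s), lang) for s, lang in forms}
        if label in self.entries:
            new_forms |= self.entries[label].forms
        for key in new_forms:
            owner = self._reverse.get(key)
            if owner is not None and owner != label:
                raise ValueError(
                    f"form {key!r} already belongs to megalemma {owner!r}"
                )
        self.entries[label] = Megalemma(label=label, forms=frozenset(new_forms))
        for key in new_forms:
            self._reverse[key] = label

    def add_megatoken(self, labels: Iterable[str]) -> Megatoken:
        mt = Megatoken(tuple(lab.upper() for lab in labels))
        unknown = [lab for lab in mt.labels if lab not in self.entries]
        if unknown:
            raise ValueError(f"megatoken references unknown megalemmas: {unknown}")
        self.megatokens.add(mt.labels)
        return mt

    def lookup(self, form: str, language: str) -> Optional[str]:
        return self._reverse.get((_norm(form), language))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MegalemmaDict):
            return NotImplemented
        return (
            self.entries == other.entries and self.megatokens == other.megatokens
        )

    # --- persistence: TSV with columns label, surface, language; megatoken
    # rows use a '+'-joined label and empty surface/language.
    def save(self, path: str | Path) -> None:
        lines = ["# label\tsurface\tlanguage"]
        for label in sorted(self.entries):
            for surface, lang in sorted(self.entries[label].forms):
                lines.append(f"{label}\t{surface}\t{lang}")
        for labels in sorted(self.megatokens):
            lines.append("+".join(labels) + "\t\t")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "MegalemmaDict":
        out = cls()
        pending_megatokens = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            label = parts[0].strip()
            if "+" in label:
                pending_megatokens.append(label.split("+"))
                continue
            surface = parts[1].strip() if len(parts) > 1 else ""
            lang = parts[2].strip() if len(parts) > 2 else "en"
            out.add(label, [(surface, lang)])
        for labels in pending_megatokens:
            out.add_megatoken(labels)
        return out


def lookup(form: str, language: str, dictionary: MegalemmaDict) -> Optional[str]:
    """Exact-match megalemma label for a normalized surface form."""
    return dictionary.lookup(form, language)


def megatoken_of(
    tokens: Sequence[str],
    language: str,
    dictionary: MegalemmaDict,
    require_known: bool = False,
) -> Optional[Megatoken]:
    """Megatoken for a word pair/group, or None if any member is unmapped.

    Order-invariant: the labels are sorted into canonical order.  With
    ``require_known`` the tuple must additionally be a dictionary-known
    megatoken.
    """
    if not tokens:
        raise ValueError("megatoken_of needs at least one token")
    labels = []
    for tok in tokens:
        lab = dictionary.lookup(tok, language)
        if lab is None:
            return None
        labels.append(lab)
    mt = Megatoken(tuple(labels))
    if require_known and mt.labels not in dictionary.megatokens:
        return None
    return mt


@dataclass
class MegatokenSequence:
    """Normalized view of a document: labels/megatokens plus coverage."""

    items: list[str | Megatoken] = field(default_factory=list)
    coverage: float = 0.0  # mapped tokens / total tokens; 0 for empty text

    def labels(self) -> list[str]:
        """Flat canonical rendering (megatokens as 'A + B')."""
        return [str(it) for it in self.items]

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


def text_to_megatokens(doc: Document, dictionary: MegalemmaDict) -> MegatokenSequence:
    """Transform a document into its megalemma/megatoken sequence.

    Tokens are mapped through the dictionary; adjacent mapped pairs whose
    label tuple is a dictionary-known megatoken are emitted as one
    megatoken; unmapped tokens are omitted from the sequence but counted in
    the coverage statistic.  Language-independent by construction: parallel
    texts built from the same megalemma labels normalize identically.
    """
    tokens: list[str] = []
    for fld in doc.fields():
        tokens.extend(tokenize(fld, doc.language, expand_hyphens=False))
    if not tokens:
        return MegatokenSequence(items=[], coverage=0.0)
    mapped = [dictionary.lookup(t, doc.language) for t in tokens]
    items: list[str | Megatoken] = []
    i = 0
    while i < len(tokens):
        lab = mapped[i]
        if lab is None:
            i += 1
            continue
        if i + 1 < len(tokens) and mapped[i + 1] is not None:
            pair = Megatoken((lab, mapped[i + 1]))
            if pair.labels in dictionary.megatokens:
                items.append(pair)
                i += 2
                continue
        items.append(lab)
        i += 1
    coverage = sum(1 for m in mapped if m is not None) / len(tokens)
    return MegatokenSequence(items=items, coverage=coverage)


class MegatokenEncoder(TransformerMixin, BaseEstimator):
    """Transformer from documents to megalemma/megatoken sequences."""

    def __init__(self, dictionary: MegalemmaDict | None = None):
        self.dictionary = dictionary

    def fit(self, X=None, y=None):
        if self.dictionary is None:
            raise ValueError("dictionary must be provided")
        return self

    def transform(self, X: Iterable[Document]) -> list[MegatokenSequence]:
        self.fit()
        return [text_to_megatokens(doc, self.dictionary) for doc in X]


# ---------------------------------------------------------------- merging

@dataclass(frozen=True)
class MergeProposal:
    label: str
    cosine: float
    context_score: float


@dataclass
class ContextSets:
    """Megalemma-label context sets observed in a corpus.

    ``words`` is keyed by (surface, language); ``megalemmas`` by label.
    """

    words: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    megalemmas: dict[str, set[str]] = field(default_factory=dict)


def build_context_sets(
    corpus: Corpus, dictionary: MegalemmaDict, window: int = 5
) -> ContextSets:
    """Collect, for every token and every megalemma, the set of megalemma
    labels seen within ``window`` positions of its occurrences."""
    ctx = ContextSets()
    for doc in corpus:
        for fld in doc.fields():
            tokens = tokenize(fld, doc.language, expand_hyphens=False)
            mapped = [dictionary.lookup(t, doc.language) for t in tokens]
            for i, tok in enumerate(tokens):
                lo = max(0, i - window)
                hi = min(len(tokens), i + window + 1)
                neigh = {
                    mapped[j] for j in range(lo, hi)
                    if j != i and mapped[j] is not None
                }
                if not neigh:
                    continue
                ctx.words.setdefault((tok, doc.language), set()).update(neigh)
                if mapped[i] is not None:
                    ctx.megalemmas.setdefault(mapped[i], set()).update(neigh)
    return ctx


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def load_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    """Read a text embedding table: token then whitespace-separated floats.

    A leading word2vec-style count/dimension header line is tolerated.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 0 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue  # header
            vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]], dtype=float)
    return vectors


def propose_merge(
    word: str,
    language: str,
    dictionary: MegalemmaDict,
    embeddings: Mapping[str, np.ndarray],
    contexts: ContextSets,
    vector_threshold: float = DEFAULT_VECTOR_THRESHOLD,
    context_threshold: float = DEFAULT_CONTEXT_THRESHOLD,
) -> list[MergeProposal]:
    """Rank megalemmas a new word could merge into.

    For each megalemma: cosine between the word's vector and the centroid
    of member vectors, and Jaccard overlap of megalemma-label context sets.
    A proposal is emitted only when both exceed their thresholds; ranking
    is by cosine, ties broken by context score then label.
    """
    word_n = _norm(word)
    if word_n not in embeddings:
        raise KeyError(f"no embedding vector for word {word_n!r}")
    wvec = embeddings[word_n]
    wctx = contexts.words.get((word_n, language), set())
    proposals = []
    for label, ml in dictionary.entries.items():
        member_vecs = [
            embeddings[s] for s in sorted(ml.surfaces()) if s in embeddings
        ]
        if not member_vecs:
            continue
        centroid = np.mean(member_vecs, axis=0)
        cos = _cosine(wvec, centroid)
        ctx_score = _jaccard(wctx, contexts.megalemmas.get(label, set()))
        if cos > vector_threshold and ctx_score > context_threshold:
            proposals.append(MergeProposal(label, cos, ctx_score))
    proposals.sort(key=lambda p: (-p.cosine, -p.context_score, p.label))
    return proposals
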