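"""Synthetic timestamped corpora with known ground truth.

Every other module is testable without any download: the generator builds
bag-of-words abstracts over a Zipf-distributed background vocabulary and
injects terms with a known onset year and exact per-year document counts,
optional collocation partners placed within the scan window with a stated
probability, and bilingual parallel snippets that share a hidden
megalemma-label sequence.

The generator returns the corpus together with the exact yearly count
table and the exact partner co-occurrence counts it realized, so trend and
discovery statistics can be checked against construction rather than
against re-measurement.

What this emulates: the sparsity and timing structure of term emergence in
abstracts (onset years, yearly counts, window collocations).  What it does
not: grammar, topical coherence, realistic morphology — a green test
establishes counting and statistics correctness, not linguistic fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Corpus, Document
from .megalemma import MegalemmaDict
from .trends import YearlyCountTable

__all__ = [
    "InjectionSpec",
    "SyntheticResult",
    "make_background_vocab",
    "generate",
    "parallel_documents",
]

#: Zipf exponent for the background vocabulary (rank-frequency slope ~1 is
#: the classic text regime; 1.1 keeps the tail thin enough at 1,000 words).
ZIPF_EXPONENT = 1.1
BACKGROUND_VOCAB_SIZE = 1000
ABSTRACT_MEAN_LENGTH = 120  # Poisson mean, tokens
TITLE_LENGTH = 6
DEFAULT_DOCS_PER_YEAR = 60
#: Filler gap between injected segments so each partner co-occurs only with
#: its own term under any window up to this size.
SEGMENT_GAP = 10


@dataclass
class InjectionSpec:
    """Ground-truth emergence schedule for one injected term.

    ``yearly_counts`` maps year -> number of documents that contain the
    term that year (the term appears exactly once per such document).
    ``partners`` maps a collocation partner surface to its placement
    probability: with that probability the partner is written immediately
    next to the term occurrence (distance 1, inside any scan window).
    """

    term: str
    onset_year: int
    yearly_counts: dict[int, int] = field(default_factory=dict)
    partners: dict[str, float] = field(default_factory=dict)
    language: str = "en"

    def __post_init__(self) -> None:
        for year, n in self.yearly_counts.items():
            if n < 0:
                raise ValueError(f"{self.term}: negative count for {year}")
            if n > 0 and year < self.onset_year:
                raise ValueError(
                    f"{self.term}: nonzero count in {year} before onset "
                    f"{self.onset_year}"
                )
        for partner, p in self.partners.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.term}/{partner}: probability {p} not in [0,1]")

    @classmethod
    def constant(
        cls,
        term: str,
        onset_year: int,
        per_year: int,
        years: tuple[int, int],
        partners: Mapping[str, float] | None = None,
    ) -> "InjectionSpec":
        """Flat schedule: ``per_year`` documents every year from onset on."""
        lo, hi = years
        return cls(
            term=term,
            onset_year=onset_year,
            yearly_counts={y: per_year for y in range(max(lo, onset_year), hi + 1)},
            partners=dict(partners or {}),
        )


@dataclass
class SyntheticResult:
    """Corpus plus the ground truth realized during generation."""

    corpus: Corpus
    truth: YearlyCountTable
    #: (term, partner) -> exact number of placements (= co-occurrence events)
    pair_counts: dict[tuple[str, str], int]
    #: (term, partner) -> year -> placements
    pair_counts_by_year: dict[tuple[str, str], dict[int, int]]
    specs: list[InjectionSpec]
    seed: int


def make_background_vocab(
    size: int = BACKGROUND_VOCAB_SIZE, prefix: str = "bgw"
) -> list[str]:
    """Background vocabulary disjoint from any realistic injected term."""
    return [f"{prefix}{i:04d}" for i in range(size)]


def _zipf_probs(size: int, exponent: float = ZIPF_EXPONENT) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks**-exponent
    return w / w.sum()


def generate(
    specs: Iterable[InjectionSpec],
    background_vocab: Sequence[str] | None = None,
    n_docs_per_year: Mapping[int, int] | None = None,
    seed: int = 0,
    years: tuple[int, int] = (2000, 2019),
) -> SyntheticResult:
    """Generate a corpus realizing the injection specs exactly.

    Documents are Zipf bag-of-words abstracts; each scheduled term
    occurrence is appended as a segment (term, optionally partner) with a
    filler gap before and between segments so co-occurrence counts are
    exact by construction.  Same seed, same corpus.
    """
    specs = list(specs)
    rng = np.random.default_rng(seed)
    lo, hi = years
    if background_vocab is None:
        background_vocab = make_background_vocab()
    vocab = np.asarray(background_vocab)
    probs = _zipf_probs(len(vocab))
    if n_docs_per_year is None:
        n_docs_per_year = {y: DEFAULT_DOCS_PER_YEAR for y in range(lo, hi + 1)}

    for spec in specs:
        for year, n in spec.yearly_counts.items():
            if not (lo <= year <= hi):
                raise ValueError(
                    f"{spec.term}: scheduled year {year} outside corpus range {years}"
                )
            if n > n_docs_per_year.get(year, 0):
                raise ValueError(
                    f"{spec.term}: {n} docs scheduled in {year} but only "
                    f"{n_docs_per_year.get(year, 0)} generated"
                )

    truth = YearlyCountTable(
        term_counts={s.term: dict(s.yearly_counts) for s in specs},
        totals=dict(sorted(n_docs_per_year.items())),
    )
    pair_counts: dict[tuple[str, str], int] = {}
    pair_by_year: dict[tuple[str, str], dict[int, int]] = {}

    documents: list[Document] = []
    for year in sorted(n_docs_per_year):
        n_docs = n_docs_per_year[year]
        # which documents carry which term this year
        carriers: dict[int, list[InjectionSpec]] = {}
        for spec in specs:
            n = spec.yearly_counts.get(year, 0)
            if n == 0:
                continue
            chosen = rng.choice(n_docs, size=n, replace=False)
            for d in chosen:
                carriers.setdefault(int(d), []).append(spec)
        for d in range(n_docs):
            length = max(10, int(rng.poisson(ABSTRACT_MEAN_LENGTH)))
            body = list(rng.choice(vocab, size=length, p=probs))
            for spec in carriers.get(d, []):
                segment = [spec.term]
                for partner in sorted(spec.partners):
                    if rng.random() < spec.partners[partner]:
                        segment.append(partner)
                        key = (spec.term, partner)
                        pair_counts[key] = pair_counts.get(key, 0) + 1
                        by_year = pair_by_year.setdefault(key, {})
                        by_year[year] = by_year.get(year, 0) + 1
                body.extend(rng.choice(vocab, size=SEGMENT_GAP, p=probs))
                body.extend(segment)
            title = " ".join(rng.choice(vocab, size=TITLE_LENGTH, p=probs))
            documents.append(
                Document(
                    doc_id=f"syn-{year}-{d:04d}",
                    year=year,
                    title=title,
                    abstract=" ".join(body),
                    language="en",
                )
            )
    return SyntheticResult(
        corpus=Corpus(documents=documents),
        truth=truth,
        pair_counts=pair_counts,
        pair_counts_by_year=pair_by_year,
        specs=specs,
        seed=seed,
    )


def parallel_documents(
    label_sequence: Sequence[str],
    dictionary: MegalemmaDict,
    languages: Sequence[str],
    year: int = 2019,
    doc_id_prefix: str = "par",
) -> list[Document]:
    """Bilingual parallel snippets sharing one megalemma-label sequence.

    For each language, every label is rendered as that language's first
    surface form (sorted order, deterministic).  The resulting documents
    normalize to identical label sequences — the language-independence
    fixture used by the megatoken tests.
    """
    docs = []
    for lang in languages:
        words = []
        for label in label_sequence:
            ml = dictionary.entries.get(label.upper())
            if ml is None:
                raise ValueError(f"unknown megalemma label {label!r}")
            surfaces = sorted(ml.surfaces(lang))
            if not surfaces:
                raise ValueError(f"megalemma {label!r} has no {lang!r} form")
            words.append(surfaces[0])
        docs.append(
            Document(
                doc_id=f"{doc_id_prefix}-{lang}",
                year=year,
                title="",
                abstract=" ".join(words),
                language=lang,
            )
        )
    return docs
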