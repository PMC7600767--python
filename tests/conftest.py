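"""Shared fixtures: toy corpora, a cross-lingual dictionary, and the
independent brute-force neighborhood counter used as oracle."""

from __future__ import annotations

import numpy as np
import pytest

from termspace.corpus import Corpus, Document, tokenize
from termspace.discovery import KeyTermDictionary
from termspace.megalemma import MegalemmaDict


@pytest.fixture
def small_corpus() -> Corpus:
    return Corpus(
        [
            Document("a1", 2007, "Predictive models", "models predicting risk accurately"),
            Document("a2", 2019, "Personalised care", "towards personalised preventive care"),
        ]
    )


@pytest.fixture
def gen_disease_dict() -> MegalemmaDict:
    """Cross-lingual dictionary around the GEN / DISEASE / VIRUS clusters."""
    d = MegalemmaDict()
    d.add("GEN", [
        ("gene", "en"), ("genetic", "en"), ("genomic", "en"), ("genome", "en"),
        ("gennye", "ru"), ("genetica", "ru"), ("genom", "ru"), ("genomica", "ru"),
    ])
    d.add("DISEASE", [
        ("disease", "en"), ("diseased", "en"), ("diseases", "en"),
        ("bolezn", "ru"), ("bolet", "ru"), ("bolnoy", "ru"),
    ])
    d.add("VIRUS", [
        ("virus", "en"), ("viruses", "en"),
        ("virusnye", "ru"), ("virusologia", "ru"),
    ])
    d.add("PATIENT", [("patient", "en"), ("patients", "en"), ("pacient", "ru")])
    d.add_megatoken(["GEN", "DISEASE"])
    d.add_megatoken(["DISEASE", "PATIENT"])
    return d


def brute_force_scan(
    corpus: Corpus, keys: KeyTermDictionary, window: int
) -> dict[tuple[str, str], int]:
    """O(n^2)-style oracle: enumerate every ordered token pair in each
    field and keep those within the window with a key on one side and a
    non-key on the other.  Independent of the scanner's single pass."""
    counts: dict[tuple[str, str], int] = {}
    for doc in corpus:
        for fld in doc.fields():
            tokens = tokenize(fld, doc.language)
            for i in range(len(tokens)):
                root = keys.match(tokens[i])
                if root is None:
                    continue
                for j in range(len(tokens)):
                    if j == i or abs(i - j) > window:
                        continue
                    if keys.match(tokens[j]) is not None:
                        continue
                    key = (root, tokens[j])
                    counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.fixture
def brute_scan_oracle():
    return brute_force_scan


def random_corpus(rng: np.random.Generator, max_tokens: int = 10_000) -> Corpus:
    """A random corpus over a tiny vocabulary rich in key-root hits."""
    vocab = (
        ["predict", "predictive", "unpredictable", "personalised", "prevention"]
        + [f"word{i}" for i in range(30)]
    )
    docs = []
    total = 0
    doc_id = 0
    while total < max_tokens:
        n = int(rng.integers(5, 60))
        total += n
        words = rng.choice(vocab, size=n)
        docs.append(
            Document(
                f"r{doc_id}",
                int(rng.integers(2000, 2020)),
                title=" ".join(words[: n // 4]) or "t",
                abstract=" ".join(words[n // 4:]),
            )
        )
        doc_id += 1
    return Corpus(docs)


@pytest.fixture
def random_corpus_factory():
    return random_corpus
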