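"""Emerging-term discovery from key-term neighborhoods.

The procedure: hold a dictionary of key roots for the subject area; scan
every document; wherever a token matches a key root (under the derivative
rule), record every other token within ``window`` positions in the same
field as a candidate new word, incrementing its neighborhood frequency and
remembering the phrase as it appeared.  Candidates whose frequency exceeds
a threshold are put before an expert (here: an accept-list) for promotion
into the main dictionary.

The result is a statistics array keyed by root: for each key root, the
candidate new words found next to it with their neighborhood frequencies,
first year of appearance, and per-year counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from sklearn.base import BaseEstimator

from .corpus import Corpus, tokenize
from .grouping import DEFAULT_PREFIXES, match_derivative

__all__ = [
    "KeyTermDictionary",
    "CandidateTerm",
    "DiscoveryTable",
    "NeighborhoodScanner",
    "scan_neighborhoods",
    "select_candidates",
    "promote",
]

DEFAULT_WINDOW = 5
DEFAULT_THRESHOLD = 5


@dataclass
class KeyTermDictionary:
    """Key roots of the subject area, each with accepted derivatives.

    ``roots`` maps a lowercase root (e.g. "predict", "personali") to the
    set of candidate surfaces an expert has promoted under it.
    """

    roots: dict[str, set[str]] = field(default_factory=dict)
    prefixes: tuple[str, ...] = DEFAULT_PREFIXES

    def __post_init__(self) -> None:
        for root in self.roots:
            if not root or root != root.lower():
                raise ValueError(f"roots must be non-empty lowercase: {root!r}")

    @classmethod
    def from_roots(cls, roots: Iterable[str]) -> "KeyTermDictionary":
        return cls(roots={r: set() for r in roots})

    @classmethod
    def load(cls, path: str | Path) -> "KeyTermDictionary":
        """Plain text, one root per line; '#' starts a comment."""
        roots = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip().lower()
            if line and not line.startswith("#"):
                roots.append(line)
        return cls.from_roots(roots)

    def match(self, token: str) -> Optional[str]:
        """The root this token belongs to (derivative rule or promoted
        surface), or None if the token is outside the dictionary."""
        for root, accepted in self.roots.items():
            if token in accepted or match_derivative(token, root, self.prefixes):
                return root
        return None

    def copy(self) -> "KeyTermDictionary":
        return KeyTermDictionary(
            roots={r: set(s) for r, s in self.roots.items()}, prefixes=self.prefixes
        )


@dataclass
class CandidateTerm:
    """A candidate new word with its neighborhood statistics."""

    surface: str
    neighborhood_count: int = 0
    first_year: Optional[int] = None
    per_year_counts: dict[int, int] = field(default_factory=dict)
    anchored_phrases: set[tuple[str, str]] = field(default_factory=set)

    def record(self, year: int, phrase: tuple[str, str]) -> None:
        self.neighborhood_count += 1
        self.per_year_counts[year] = self.per_year_counts.get(year, 0) + 1
        self.first_year = year if self.first_year is None else min(self.first_year, year)
        self.anchored_phrases.add(phrase)


@dataclass
class DiscoveryTable:
    """Per-root candidate statistics: the discovery array."""

    entries: dict[str, dict[str, CandidateTerm]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def candidate(self, root: str, surface: str) -> CandidateTerm:
        by_surface = self.entries.setdefault(root, {})
        if surface not in by_surface:
            by_surface[surface] = CandidateTerm(surface=surface)
        return by_surface[surface]

    def count(self, root: str, surface: str) -> int:
        cand = self.entries.get(root, {}).get(surface)
        return cand.neighborhood_count if cand else 0

    def surfaces(self) -> set[str]:
        return {s for by_surface in self.entries.values() for s in by_surface}

    def select(self, threshold: int = DEFAULT_THRESHOLD) -> "DiscoveryTable":
        """Restrict to candidates with count strictly above the threshold."""
        out = DiscoveryTable(meta={**self.meta, "threshold": threshold})
        for root, by_surface in self.entries.items():
            kept = {
                s: c for s, c in by_surface.items()
                if c.neighborhood_count > threshold
            }
            if kept:
                out.entries[root] = kept
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "root": root,
                "candidate": cand.surface,
                "count": cand.neighborhood_count,
                "first_year": cand.first_year,
                "per_year_counts": json.dumps(
                    {str(y): n for y, n in sorted(cand.per_year_counts.items())}
                ),
            }
            for root, by_surface in sorted(self.entries.items())
            for cand in sorted(by_surface.values(), key=lambda c: (-c.neighborhood_count, c.surface))
        ]
        return pd.DataFrame(
            rows, columns=["root", "candidate", "count", "first_year", "per_year_counts"]
        )


def scan_neighborhoods(
    corpus: Corpus,
    keys: KeyTermDictionary,
    window: int = DEFAULT_WINDOW,
    years: tuple[int, int] | None = None,
) -> DiscoveryTable:
    """Build the discovery array by scanning key-term neighborhoods.

    For every token matching a key root, every other token within
    ``window`` positions in the same field (title or abstract — windows
    never cross the boundary) that is itself outside the key dictionary is
    recorded as a candidate, once per co-occurrence event.  Phrases are
    stored as ordered pairs in their textual order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not keys.roots:
        raise ValueError("empty key dictionary")
    table = DiscoveryTable(meta={"window": window, "years": years})
    for doc in corpus:
        if years is not None and not (years[0] <= doc.year <= years[1]):
            continue
        for fld in doc.fields():
            tokens = tokenize(fld, doc.language)
            n = len(tokens)
            # cache per-token dictionary match for this field
            matched = [keys.match(t) for t in tokens]
            for i, root in enumerate(matched):
                if root is None:
                    continue
                lo = max(0, i - window)
                hi = min(n, i + window + 1)
                for j in range(lo, hi):
                    if j == i or matched[j] is not None:
                        continue
                    phrase = (tokens[i], tokens[j]) if i < j else (tokens[j], tokens[i])
                    table.candidate(root, tokens[j]).record(doc.year, phrase)
    return table


def select_candidates(
    table: DiscoveryTable, threshold: int = DEFAULT_THRESHOLD
) -> DiscoveryTable:
    """Candidates with neighborhood frequency strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return table.select(threshold)


def promote(
    keys: KeyTermDictionary,
    accepted: Iterable[str],
    table: DiscoveryTable,
) -> KeyTermDictionary:
    """Append expert-accepted candidate surfaces to the main dictionary.

    Append-only and idempotent; each accepted surface is attached under
    every root it was discovered with.  Accepting a surface the discovery
    table has never seen is an error.
    """
    accepted = set(accepted)
    unseen = accepted - table.surfaces()
    if unseen:
        raise ValueError(f"never-seen candidate surfaces: {sorted(unseen)}")
    out = keys.copy()
    for root, by_surface in table.entries.items():
        out.roots.setdefault(root, set()).update(accepted & set(by_surface))
    return out


class NeighborhoodScanner(BaseEstimator):
    """Estimator wrapper around the neighborhood scan.

    ``fit(corpus)`` builds the full discovery array (``table_``) and its
    thresholded restriction (``selected_``).
    """

    def __init__(
        self,
        keys: KeyTermDictionary | None = None,
        window: int = DEFAULT_WINDOW,
        threshold: int = DEFAULT_THRESHOLD,
        years: tuple[int, int] | None = None,
    ):
        self.keys = keys
        self.window = window
        self.threshold = threshold
        self.years = years

    def fit(self, X: Corpus, y=None):
        if self.keys is None:
            raise ValueError("keys must be provided")
        self.table_ = scan_neighborhoods(X, self.keys, self.window, self.years)
        self.selected_ = select_candidates(self.table_, self.threshold)
        return self
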