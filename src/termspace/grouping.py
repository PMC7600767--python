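"""Root-derivative families, collocation classes and sphere categories.

A *derivative* is a surface form sharing a root with a key term, allowing an
optional prefix (un-, non-, de-) and any suffix, with the s/z orthographic
interchange (so "personalise" and "personalize" both match the root
"personali").  Collocations — word pairs from the window scan — fall into
three classes:

* ``random``: one member is a function word or auxiliary ("also predicted");
  a window artifact, excluded from the semantic map.
* ``megatoken_forming``: both members map to megalemmas, so the pair
  normalizes to a megatoken (e.g. "prediction model" -> PREDICT + MODEL).
* ``independent``: a genuine collocation that has not (yet) formed a
  megatoken ("predict future").

Categorized items get one of six fixed sphere categories.  For the two
minor roots (prognosis-like and prevention-like) derivatives and
collocations share a single mixed category each, because those families are
too small to split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .megalemma import MegalemmaDict, Megatoken

__all__ = [
    "DerivativeFamily",
    "CollocationRecord",
    "Category",
    "CATEGORIES",
    "DEFAULT_ROOTS",
    "DEFAULT_PREFIXES",
    "load_stop_patterns",
    "match_derivative",
    "group_derivatives",
    "classify_collocation",
    "assign_category",
]

#: Configured key roots, in category order.
DEFAULT_ROOTS = ("predict", "personali", "prognos", "prevent")

#: Prefixes covering every printed derivative (unpredictable,
#: depersonalization, non-...); extendable per call.
DEFAULT_PREFIXES = ("un", "non", "de")

RANDOM = "random"
MEGATOKEN_FORMING = "megatoken_forming"
INDEPENDENT = "independent"


@dataclass(frozen=True)
class Category:
    index: int  # 1-6
    root: str
    kind: str  # derivative | megatoken | mixed
    color: str  # color name; hex lives in the scene exporter


#: The six fixed (index, color) sphere categories.
CATEGORIES: tuple[Category, ...] = (
    Category(1, "predict", "derivative", "purple"),
    Category(2, "predict", "megatoken", "green"),
    Category(3, "personali", "derivative", "black"),
    Category(4, "personali", "megatoken", "blue"),
    Category(5, "prognos", "mixed", "red"),
    Category(6, "prevent", "mixed", "yellow"),
)

_MIXED_ROOTS = frozenset(c.root for c in CATEGORIES if c.kind == "mixed")


@dataclass
class DerivativeFamily:
    """All vocabulary forms matching one root, with their counts."""

    root: str
    members: dict[str, int] = field(default_factory=dict)
    relative_growth: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CollocationRecord:
    """An ordered word pair with its window co-occurrence statistics."""

    tokens: tuple[str, str]
    count: int
    years: dict[int, int] = field(default_factory=dict)
    classification: Optional[str] = None
    megatoken: Optional["Megatoken"] = None
    relative_growth: Optional[float] = None

    def __post_init__(self) -> None:
        self.tokens = tuple(self.tokens)  # type: ignore[assignment]
        if len(self.tokens) != 2:
            raise ValueError("a collocation is an ordered pair of tokens")


def load_stop_patterns(path: str | Path | None = None) -> frozenset[str]:
    """Load the editable stop-pattern list (default: packaged resource)."""
    if path is None:
        text = (
            resources.files("termspace").joinpath("data/stop_patterns.txt")
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    out = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return frozenset(out)


def _sz(a: str, b: str) -> bool:
    return a == b or {a, b} == {"s", "z"}


def _stem_matches(stem: str, root: str) -> bool:
    # stem = root (with s/z interchange) + arbitrary suffix
    if len(stem) < len(root):
        return False
    return all(_sz(a, b) for a, b in zip(stem, root))


def match_derivative(
    word: str, root: str, prefixes: Iterable[str] = DEFAULT_PREFIXES
) -> bool:
    """True iff ``word`` is a derivative of ``root``.

    The word may carry one optional prefix from ``prefixes`` and any
    suffix; the stem must reproduce the root letter-for-letter up to the
    s/z interchange.  Examples: "unpredictability" matches "predict";
    "personalised" matches "personali"; "prediabetes" does not match
    "predict" (stem diverges).
    """
    if _stem_matches(word, root):
        return True
    return any(
        word.startswith(p) and _stem_matches(word[len(p):], root)
        for p in prefixes
    )


def group_derivatives(
    vocabulary: Mapping[str, int],
    root: str,
    prefixes: Iterable[str] = DEFAULT_PREFIXES,
) -> DerivativeFamily:
    """Collect every vocabulary token that derives from ``root``."""
    prefixes = tuple(prefixes)
    members = {
        w: c for w, c in vocabulary.items() if match_derivative(w, root, prefixes)
    }
    return DerivativeFamily(root=root, members=members)


def classify_collocation(
    record: CollocationRecord,
    roots: Iterable[str] = DEFAULT_ROOTS,
    stop_patterns: frozenset[str] | None = None,
    megalemmas: "MegalemmaDict | None" = None,
    language: str = "en",
) -> str:
    """Classify a collocation and annotate the record in place.

    ``random`` when either member is a stop pattern; else
    ``megatoken_forming`` when both members map to megalemmas (the
    megatoken is attached to the record); else ``independent``.
    """
    if record.count <= 0:
        raise ValueError("collocation record must have positive count")
    if stop_patterns is None:
        stop_patterns = load_stop_patterns()
    a, b = record.tokens
    if a in stop_patterns or b in stop_patterns:
        record.classification = RANDOM
        record.megatoken = None
        return RANDOM
    if megalemmas is not None:
        from .megalemma import megatoken_of

        mt = megatoken_of(record.tokens, language, megalemmas)
        if mt is not None:
            record.classification = MEGATOKEN_FORMING
            record.megatoken = mt
            return MEGATOKEN_FORMING
    record.classification = INDEPENDENT
    record.megatoken = None
    return INDEPENDENT


def _root_of(tokens: Iterable[str], roots: Iterable[str]) -> str | None:
    for root in roots:
        for tok in tokens:
            if match_derivative(tok, root):
                return root
    return None


def assign_category(
    item: str | CollocationRecord,
    roots: Iterable[str] = DEFAULT_ROOTS,
) -> Category:
    """Map a derivative form or a non-random collocation to its category.

    The scheme is positional over the configured roots (at most four):
    the first two — the numerous roots — split into a derivative and a
    megatoken category each (indices 1/2 and 3/4); the last two — the
    small families — get one mixed category each (indices 5 and 6).
    Colors follow the fixed six-category palette.  Single word forms go
    to the derivative category, collocations to the megatoken one.
    """
    roots = tuple(roots)
    if len(roots) > 4:
        raise ValueError("the six-category scheme supports at most four roots")
    if isinstance(item, CollocationRecord):
        if item.classification == RANDOM:
            raise ValueError("random collocations are excluded from the map")
        root = _root_of(item.tokens, roots)
        kind = "megatoken"
    else:
        root = _root_of([item], roots)
        kind = "derivative"
    if root is None:
        raise ValueError(f"item {item!r} matches no configured root {roots}")
    pos = roots.index(root)
    if pos < 2:
        index = 2 * pos + (1 if kind == "derivative" else 2)
    else:
        index, kind = pos + 3, "mixed"
    cat = CATEGORIES[index - 1]
    return Category(index=index, root=root, kind=kind, color=cat.color)
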