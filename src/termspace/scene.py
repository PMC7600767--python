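"""3D semantic-map ("cyberspace") construction and export.

Each categorized term becomes a sphere: its *rating* (window occurrence
count) sets the radius through a log map so that terms spanning two orders
of magnitude of frequency stay co-visible; its position comes from a
variance-maximizing linear projection (PCA) of its embedding vector to
three axes; its color is fixed by the six-category scheme.  The scene is
written as a JSON document plus an HTML wrapper with A-Frame-style sphere
entities; re-export of identical inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .grouping import CATEGORIES, Category

__all__ = [
    "SceneNode",
    "SemanticLayout",
    "COLOR_HEX",
    "R_MIN",
    "RADIUS_K",
    "BOX_HALF",
    "compute_rating",
    "radius_for",
    "layout_3d",
    "fit_box",
    "make_node",
    "export_scene",
]

#: Fixed color hexes for the six categories.
COLOR_HEX = {
    "purple": "#800080",
    "green": "#008000",
    "black": "#000000",
    "blue": "#0000FF",
    "red": "#FF0000",
    "yellow": "#FFFF00",
}

R_MIN = 0.1     # scene units; radius of a rating-0 sphere
RADIUS_K = 0.25  # log-scale gain
BOX_HALF = 10.0  # coordinates fit the [-10, 10]^3 box


@dataclass(frozen=True)
class SceneNode:
    """One term sphere."""

    label: str
    rating: float
    radius: float
    coords: tuple[float, float, float]
    color: str  # hex
    category_index: int

    def __post_init__(self) -> None:
        if self.rating < 0:
            raise ValueError("rating must be non-negative")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if len(self.coords) != 3:
            raise ValueError("coords must be 3D")
        if not (1 <= self.category_index <= 6):
            raise ValueError("category index must be 1-6")


def compute_rating(stats: Mapping[int, float] | float) -> float:
    """A term's prominence: its total occurrence count in the window.

    Accepts a per-year count mapping or a plain total.  Higher rating =>
    larger sphere; deterministic and config-free by default.
    """
    if isinstance(stats, Mapping):
        total = float(sum(stats.values()))
    else:
        total = float(stats)
    if total < 0:
        raise ValueError("counts must be non-negative")
    return total


def radius_for(rating: float) -> float:
    """Monotone log map from rating to sphere radius (scene units)."""
    return R_MIN + RADIUS_K * float(np.log1p(rating))


class SemanticLayout(TransformerMixin, BaseEstimator):
    """Variance-maximizing linear projection of embeddings to 3 axes.

    Vectors are centered; with more than three input dimensions a full-SVD
    PCA keeps the top three components (deterministic sign convention);
    with three or fewer the centered vectors are kept as-is and padded with
    zero axes, so already-3D input passes through up to centering.  The
    seed only matters for degenerate-axis resolution and is recorded, not
    consumed, in the non-degenerate path.
    """

    def __init__(self, n_components: int = 3, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D array of vectors")
        n, d = X.shape
        centered = X - X.mean(axis=0)
        k = self.n_components
        if d <= k:
            out = np.zeros((n, k))
            out[:, :d] = centered
            self.components_ = np.eye(d, k).T
            return out
        rank = min(n, d)
        pca = PCA(
            n_components=min(k, rank), svd_solver="full",
            random_state=self.seed,
        )
        # fit + transform (not fit_transform): the latter returns U*S from
        # the SVD, which is not row-wise reproducible for duplicate inputs
        pca.fit(X)
        proj = pca.transform(X)
        self.components_ = pca.components_
        if proj.shape[1] < k:
            proj = np.hstack([proj, np.zeros((n, k - proj.shape[1]))])
        return proj

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def layout_3d(
    vectors: Mapping[str, Sequence[float]], seed: int = 0
) -> dict[str, tuple[float, float, float]]:
    """Project per-term embedding vectors to 3D coordinates.

    All vectors must share one dimension; identical input vectors receive
    identical coordinates.  Coordinates are *not* box-scaled here — that
    happens when the scene is assembled — so already-3D centered input
    comes back unchanged.
    """
    if not vectors:
        raise ValueError("need at least one vector")
    terms = list(vectors)
    dims = {len(vectors[t]) for t in terms}
    if len(dims) != 1:
        raise ValueError(f"embedding dimension mismatch: {sorted(dims)}")
    X = np.asarray([vectors[t] for t in terms], dtype=float)
    proj = SemanticLayout(n_components=3, seed=seed).fit_transform(X)
    return {t: tuple(map(float, row)) for t, row in zip(terms, proj)}


def fit_box(
    coords: Mapping[str, tuple[float, float, float]], half: float = BOX_HALF
) -> dict[str, tuple[float, float, float]]:
    """Uniformly rescale coordinates to fit the [-half, half]^3 box."""
    arr = np.asarray(list(coords.values()), dtype=float)
    max_abs = float(np.max(np.abs(arr))) if arr.size else 0.0
    scale = half / max_abs if max_abs > 0 else 1.0
    return {
        t: tuple(float(c * scale) for c in xyz) for t, xyz in coords.items()
    }


def make_node(
    label: str,
    rating: float,
    coords: tuple[float, float, float],
    category: Category,
) -> SceneNode:
    """Assemble a sphere from its statistics, position and category."""
    return SceneNode(
        label=label,
        rating=float(rating),
        radius=radius_for(rating),
        coords=tuple(float(c) for c in coords),
        color=COLOR_HEX[category.color],
        category_index=category.index,
    )


def _node_dict(node: SceneNode) -> dict:
    x, y, z = (round(c, 6) for c in node.coords)
    return {
        "label": node.label,
        "radius": round(node.radius, 6),
        "x": x,
        "y": y,
        "z": z,
        "color": node.color,
        "category": node.category_index,
    }


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>termspace semantic map</title>
<script src="https://aframe.io/releases/1.4.0/aframe.min.js"></script>
</head>
<body>
<a-scene background="color: #ECECEC">
{entities}
<a-entity camera look-controls wasd-controls position="0 0 25"></a-entity>
</a-scene>
</body>
</html>
"""


def export_scene(
    nodes: Iterable[SceneNode],
    path: str | Path,
    allow_empty: bool = False,
    meta: Mapping | None = None,
) -> Path:
    """Write the scene JSON and its HTML wrapper.

    ``path`` names the JSON file; the wrapper is written alongside with an
    ``.html`` suffix.  Output is deterministic: nodes sorted by label,
    fixed float rounding, sorted keys — identical inputs re-export
    byte-identically.
    """
    nodes = sorted(nodes, key=lambda n: n.label)
    if not nodes and not allow_empty:
        raise ValueError("empty node set (pass allow_empty=True to permit)")
    path = Path(path)
    doc = {
        "meta": dict(sorted((meta or {}).items())),
        "nodes": [_node_dict(n) for n in nodes],
    }
    path.write_text(
        json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    entities = "\n".join(
        '<a-sphere position="{x} {y} {z}" radius="{radius}" color="{color}" '
        'data-label="{label}" data-category="{category}"></a-sphere>'.format(**_node_dict(n))
        for n in nodes
    )
    html_path = path.with_suffix(".html")
    html_path.write_text(_HTML_TEMPLATE.format(entities=entities), encoding="utf-8")
    return path
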