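"""Feature construction and 2-D embedding of violating focus nodes.

Focus nodes that violate the same constraints should land near each other in
the plane, so that clusters in a scatterplot correspond to shared error
patterns.  Two feature sets are supported: *violations* (a binary matrix of
which constraints each node violates — gives the cleanest separation by
violated constraint) and *full* (violations plus one-hot/standardized
instance features — can split a shared pattern into subclusters driven by
differing triggering values).

The embedding is UMAP with a fixed seed; quality is asserted through
distances and silhouette, never through absolute coordinates, because those
are environment-sensitive.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from sklearn.metrics import silhouette_score

from .tabular import FocusTable

DEFAULT_SEED = 42
DEFAULT_MIN_DIST = 0.1
MAX_NEIGHBORS = 15


class EmptyTableError(ValueError):
    """No rows to build features from."""


class EmbeddingParameterError(ValueError):
    """Embedding parameters incompatible with the matrix size."""


@dataclass(frozen=True)
class FeatureMatrix:
    rows: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray  # shape (len(rows), len(columns))
    mode: str  # "violations" | "full"


@dataclass(frozen=True)
class Embedding:
    rows: tuple[str, ...]
    coordinates: np.ndarray  # shape (len(rows), 2)
    seed: int
    n_neighbors: int
    min_dist: float


def build_feature_matrix(table: FocusTable, mode: str = "violations") -> FeatureMatrix:
    """Numeric features per focus node, aligned with the table's row order.

    violations mode: the indicator block as a 0/1 matrix.
    full mode: indicators plus a one-hot column per (data column, value) for
    non-numeric columns (absent value = all zeros; multi-valued cells set
    several positions) and a z-scored column per numeric data column
    (missing entries imputed at the column mean, i.e., z = 0).
    """
    if mode not in ("violations", "full"):
        raise ValueError(f"unknown feature mode {mode!r}")
    if not table.rows:
        raise EmptyTableError("cannot build features from an empty table")

    columns: list[str] = list(table.indicator_columns)
    blocks = [np.array(
        [[1.0 if table.indicator(row, c) else 0.0 for c in table.indicator_columns]
         for row in table.rows]
    )]

    if mode == "full":
        kinds = table.column_kinds or {}
        for column in table.data_columns:
            if kinds.get(column) == "numeric":
                raw = []
                for row in table.rows:
                    cell = table.cell(row, column)
                    raw.append(float(next(iter(cell)).value) if cell else np.nan)
            else:
                levels = sorted({v for row in table.rows for v in table.cell_texts(row, column)})
                for level in levels:
                    columns.append(f"{column}={level}")
                block = np.array(
                    [[1.0 if level in table.cell_texts(row, column) else 0.0 for level in levels]
                     for row in table.rows]
                )
                if levels:
                    blocks.append(block)
                continue
            values = np.asarray(raw, dtype=float)
            mean = np.nanmean(values) if np.any(~np.isnan(values)) else 0.0
            std = np.nanstd(values)
            values = np.where(np.isnan(values), mean, values)
            values = (values - mean) / std if std > 0 else np.zeros_like(values)
            columns.append(column)
            blocks.append(values[:, None])

    matrix = np.hstack(blocks) if blocks else np.zeros((len(table.rows), 0))
    return FeatureMatrix(
        rows=tuple(table.rows), columns=tuple(columns), values=matrix, mode=mode
    )


def embed_2d(
    matrix: FeatureMatrix,
    seed: int = DEFAULT_SEED,
    n_neighbors: Optional[int] = None,
    min_dist: float = DEFAULT_MIN_DIST,
) -> Embedding:
    """Seeded UMAP embedding of the feature matrix into the plane.

    The default neighborhood is ``min(15, rows - 1)``.  With a fixed seed the
    coordinates are deterministic within one software environment.
    """
    n_rows = len(matrix.rows)
    if n_rows < 2:
        raise EmbeddingParameterError("embedding needs at least 2 rows")
    if n_neighbors is None:
        n_neighbors = min(MAX_NEIGHBORS, n_rows - 1)
    if n_neighbors >= n_rows:
        raise EmbeddingParameterError(
            f"n_neighbors={n_neighbors} requires more than {n_neighbors} rows "
            f"(got {n_rows}); use a smaller neighborhood"
        )

    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # trade is exactly what reproducible preprocessing wants.
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        coords = reducer.fit_transform(matrix.values)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return Embedding(
        rows=matrix.rows, coordinates=coords, seed=seed,
        n_neighbors=n_neighbors, min_dist=min_dist,
    )


def pattern_silhouette(embedding: Embedding, patterns: Mapping[str, object]) -> float:
    """Silhouette coefficient of the embedding under pattern labels.

    ``patterns`` maps every embedded row to a hashable label (typically its
    violated-constraint set).  Raises when fewer than two labels occur, where
    the score is undefined.
    """
    labels = [patterns[row] for row in embedding.rows]
    uniq = sorted({str(l) for l in labels})
    if len(uniq) < 2:
        raise ValueError("silhouette is undefined for a single pattern label")
    encoded = np.array([uniq.index(str(l)) for l in labels])
    return float(silhouette_score(embedding.coordinates, encoded))


def separation_ratio(embedding: Embedding, patterns: Mapping[str, object]) -> tuple[float, float]:
    """(mean within-pattern distance, mean between-pattern distance) over all
    point pairs — the projection is useful when the first is smaller."""
    coords = embedding.coordinates
    labels = [str(patterns[row]) for row in embedding.rows]
    within, between = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            (within if labels[i] == labels[j] else between).append(d)
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return mean(within), mean(between)


def embedding_to_csv(
    embedding: Embedding,
    path: str | Path,
    patterns: Optional[Mapping[str, object]] = None,
) -> None:
    lines = ["focus_node,x,y,pattern_id"]
    pattern_ids: dict[str, int] = {}
    for row, (x, y) in zip(embedding.rows, embedding.coordinates):
        pid = ""
        if patterns is not None:
            key = str(patterns[row])
            pid = str(pattern_ids.setdefault(key, len(pattern_ids)))
        lines.append(f"{row},{float(x)!r},{float(y)!r},{pid}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def embedding_to_json(embedding: Embedding) -> str:
    return json.dumps({
        "seed": embedding.seed,
        "n_neighbors": embedding.n_neighbors,
        "min_dist": embedding.min_dist,
        "points": [
            {"focus_node": row, "x": float(x), "y": float(y)}
            for row, (x, y) in zip(embedding.rows, embedding.coordinates)
        ],
    }, indent=2, ensure_ascii=False)
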