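"""Reference-trained 2D embedding with out-of-sample projection and serialization.

The reference table is standardized and embedded into a 2D Euclidean plane
with UMAP; the fitted model then projects new (generated) rows into the same
plane without refitting.  A fixed seed is mandatory: every fit is exactly
reproducible, and projections through a fitted model are deterministic, which
is what makes the two-party exchange workflow auditable — the model file and
coordinate CSVs written here are exactly the artifacts one institution shares
with another.

The label column is never part of the embedding input: generated rows may
lack a label yet must pass through the same projection, so class structure
has to emerge from the features alone.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tabular_core import NormalizerStats, SchemaError, TabularDataset, fit_normalizer

_MODEL_FORMAT_VERSION = 1
_MODEL_MAGIC = b"PSDG-EMBEDDING-MODEL"


@dataclass(frozen=True)
class EmbeddingHyperparameters:
    """UMAP settings; the output space is always 2D Euclidean."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    metric: str = "euclidean"

    def __post_init__(self):
        if self.n_components != 2:
            raise ValueError("embedding space is 2D by construction")
        if self.metric != "euclidean":
            raise ValueError("embedding metric must be euclidean")


@dataclass
class Coordinates2D:
    """Identifiers paired with finite 2D points."""

    ids: list[str]
    points: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be N x 2")
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids,
                             "c1": self.points[:, 0],
                             "c2": self.points[:, 1]})


@dataclass
class EmbeddingModel:
    """A normalizer plus a fitted 2D projector trained on a reference table."""

    normalizer: NormalizerStats
    feature_order: list[str]
    hyperparameters: EmbeddingHyperparameters
    seed: int
    fitted_state: object  # trained umap.UMAP
    training_coords: Coordinates2D


def fit_embedding(reference: TabularDataset,
                  hyperparameters: EmbeddingHyperparameters | None = None,
                  seed: int = 0) -> EmbeddingModel:
    """Standardize the reference features (label excluded) and fit the 2D map.

    Requires a complete reference with more rows than ``n_neighbors``.  The
    seed fixes the UMAP random state; refitting with identical data,
    hyperparameters and seed reproduces the training coordinates
    bit-identically.
    """
    import umap  # deferred: numba compilation on first import

    hp = hyperparameters or EmbeddingHyperparameters()
    if reference.d_U:
        raise SchemaError("embedding must be trained on a complete reference")
    if reference.n_rows <= hp.n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={hp.n_neighbors} rows, got {reference.n_rows}")
    normalizer = fit_normalizer(reference)
    order = list(reference.feature_names)
    X = normalizer.transform(reference.feature_matrix(order), order)
    reducer = umap.UMAP(n_neighbors=hp.n_neighbors, min_dist=hp.min_dist,
                        n_components=2, metric=hp.metric, random_state=seed)
    emb = reducer.fit_transform(X)
    coords = Coordinates2D(reference.row_ids, emb)
    return EmbeddingModel(normalizer, order, hp, seed, reducer, coords)


def project(model: EmbeddingModel, dataset: TabularDataset) -> Coordinates2D:
    """Project rows through the fitted model; pure with respect to the model.

    Every feature in ``model.feature_order`` must be present and fully
    observed (generated candidates fill the unknown slot before projection).
    """
    missing = [n for n in model.feature_order if n not in dataset.feature_names]
    if missing:
        raise SchemaError(f"dataset lacks feature(s) {missing} required by the model")
    X = dataset.feature_matrix(model.feature_order)
    if np.isnan(X).any():
        bad = [model.feature_order[j] for j in np.unique(np.argwhere(np.isnan(X))[:, 1])]
        raise SchemaError(f"missing values in projected rows (features {bad})")
    Xn = model.normalizer.transform(X, model.feature_order)
    pts = model.fitted_state.transform(Xn)
    return Coordinates2D(dataset.row_ids, pts)


# -- serialization -------------------------------------------------------

def save_model(model: EmbeddingModel, path) -> None:
    """Write the model as a plain-text JSON header followed by a pickle payload.

    The header records the format version, hyperparameters, seed, feature
    order and normalizer stats so a recipient can audit the file without
    unpickling it.
    """
    header = {
        "format_version": _MODEL_FORMAT_VERSION,
        "hyperparameters": {
            "n_neighbors": model.hyperparameters.n_neighbors,
            "min_dist": model.hyperparameters.min_dist,
            "n_components": model.hyperparameters.n_components,
            "metric": model.hyperparameters.metric,
        },
        "seed": model.seed,
        "feature_order": model.feature_order,
        "normalizer": {
            "feature_names": list(model.normalizer.feature_names),
            "location": model.normalizer.location.tolist(),
            "scale": model.normalizer.scale.tolist(),
        },
    }
    payload = pickle.dumps(
        {"fitted_state": model.fitted_state,
         "training_ids": model.training_coords.ids,
         "training_points": model.training_coords.points},
        protocol=pickle.HIGHEST_PROTOCOL)
    with open(path, "wb") as fh:
        fh.write(_MODEL_MAGIC + b"\n")
        fh.write(json.dumps(header).encode() + b"\n")
        fh.write(payload)


def load_model(path) -> EmbeddingModel:
    """Read a model file written by :func:`save_model`."""
    raw = Path(path).read_bytes()
    nl1 = raw.find(b"\n")
    if nl1 < 0 or raw[:nl1] != _MODEL_MAGIC:
        raise ValueError(f"{path}: not a psdg embedding model file")
    nl2 = raw.find(b"\n", nl1 + 1)
    if nl2 < 0:
        raise ValueError(f"{path}: truncated model file (missing header)")
    try:
        header = json.loads(raw[nl1 + 1:nl2])
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt model header") from exc
    if header.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {header.get('format_version')}")
    try:
        payload = pickle.loads(raw[nl2 + 1:])
    except Exception as exc:
        raise ValueError(f"{path}: truncated or corrupt model payload") from exc
    norm = header["normalizer"]
    normalizer = NormalizerStats(tuple(norm["feature_names"]),
                                 np.asarray(norm["location"], dtype=float),
                                 np.asarray(norm["scale"], dtype=float))
    hp = EmbeddingHyperparameters(**header["hyperparameters"])
    coords = Coordinates2D(payload["training_ids"], payload["training_points"])
    return EmbeddingModel(normalizer, list(header["feature_order"]), hp,
                          int(header["seed"]), payload["fitted_state"], coords)


def export_coords(coords: Coordinates2D, path) -> None:
    """Write coordinates as CSV ``id,c1,c2`` at full float precision."""
    with open(path, "w", newline="") as fh:
        fh.write("id,c1,c2\n")
        for i, (c1, c2) in zip(coords.ids, coords.points):
            fh.write(f"{i},{float(c1)!r},{float(c2)!r}\n")


def import_coords(path) -> Coordinates2D:
    """Read a coordinates CSV written by :func:`export_coords`; round-trip exact."""
    ids: list[str] = []
    pts: list[tuple[float, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "id,c1,c2":
            raise ValueError(f"{path}:1: expected header 'id,c1,c2', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                pts.append((float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            ids.append(parts[0])
    return Coordinates2D(ids, np.asarray(pts, dtype=float).reshape(-1, 2))
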