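"""Cluster validation: assign class labels to projected points via per-class
circular areas in the embedding plane.

Reference points of each class define a centroid (coordinate mean, no
trimming) and a radius: the largest radius on an explicit search grid at
which the density of same-class points inside the circle still meets a
threshold.  Density is points per unit area, count / (pi r^2), so raising the
threshold shrinks the area — the behavior the method relies on to exclude
peripheral, ambiguous samples.  A raw-count reading of "density" is kept
behind ``density_mode="count"`` for comparison, where the circle must simply
contain at least ``threshold`` members.

Projected points inside exactly one area take that class; inside several, the
nearest centroid wins (ties to the lexicographically smallest label); inside
none, the point is left unassigned — unassigned is a value, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import Coordinates2D

#: marker for queries outside every cluster area
UNASSIGNED = None


@dataclass(frozen=True)
class RadiusGrid:
    """Explicit radius search grid (r_start, r_step, r_max).

    ``r_max=None`` extends the grid to the farthest member distance plus one
    step, so a zero threshold always covers the whole cluster.
    """

    r_start: float = 0.05
    r_step: float = 0.05
    r_max: float | None = None

    def __post_init__(self):
        if self.r_step <= 0:
            raise ValueError("r_step must be positive")

    def radii(self, max_member_distance: float) -> np.ndarray:
        r_max = self.r_max if self.r_max is not None else max_member_distance + self.r_step
        n = int(math.floor((r_max - self.r_start) / self.r_step + 1e-12)) + 1
        if n < 1:
            return np.asarray([self.r_start])
        return self.r_start + self.r_step * np.arange(n)


@dataclass(frozen=True)
class ClusterSpec:
    """One class's validated area: centroid, radius and the fitting threshold."""

    label: object
    centroid: tuple[float, float]
    radius: float
    density_threshold: float
    n_members: int


def compute_centroids(reference_coords: Coordinates2D,
                      labels: Sequence) -> dict:
    """Per-label arithmetic mean of member coordinates (no outlier trimming)."""
    labels = np.asarray(labels)
    if len(labels) != len(reference_coords):
        raise ValueError("labels must align with reference coordinates")
    if len(labels) == 0:
        raise ValueError("empty label set")
    out = {}
    for lab in np.unique(labels):
        pts = reference_coords.points[labels == lab]
        out[_as_label(lab)] = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    return out


def fit_radius(centroid: tuple[float, float],
               member_coords: np.ndarray,
               density_threshold: float,
               radius_grid: RadiusGrid = RadiusGrid(),
               density_mode: str = "area") -> float:
    """Largest grid radius whose enclosed member density meets the threshold.

    ``density(r) = |{members within r of centroid}| / (pi r^2)`` in the
    default per-area mode.  Returns 0 (an empty area) when no grid radius
    qualifies.  Invariant to member ordering.
    """
    member_coords = np.asarray(member_coords, dtype=float)
    if member_coords.size == 0:
        raise ValueError("empty member list")
    if density_mode not in ("area", "count"):
        raise ValueError(f"unknown density_mode {density_mode!r}")
    dist = np.hypot(member_coords[:, 0] - centroid[0], member_coords[:, 1] - centroid[1])
    best = 0.0
    for r in radius_grid.radii(float(dist.max())):
        inside = int(np.count_nonzero(dist <= r))
        density = inside / (math.pi * r * r) if density_mode == "area" else float(inside)
        if density >= density_threshold:
            best = float(r)
    return best


def fit_clusters(reference_coords: Coordinates2D,
                 labels: Sequence,
                 density_threshold: float,
                 radius_grid: RadiusGrid = RadiusGrid(),
                 density_mode: str = "area") -> list[ClusterSpec]:
    """Fit a centroid + radius area for every class present in the reference."""
    labels = np.asarray(labels)
    centroids = compute_centroids(reference_coords, labels)
    clusters = []
    for lab, centroid in sorted(centroids.items(), key=lambda kv: str(kv[0])):
        members = reference_coords.points[np.asarray([_as_label(x) for x in labels],
                                                     dtype=object) == lab]
        radius = fit_radius(centroid, members, density_threshold, radius_grid,
                            density_mode)
        clusters.append(ClusterSpec(lab, centroid, radius, density_threshold,
                                    len(members)))
    return clusters


def assign_labels(query_coords: Coordinates2D,
                  clusters: Sequence[ClusterSpec]) -> list:
    """Label each query by the cluster area(s) containing it.

    Inside one area: that label.  Inside several: nearest centroid, ties to
    the lexicographically smallest label.  Inside none: ``None``.
    """
    n = len(query_coords)
    result: list = [UNASSIGNED] * n
    if not clusters:
        return result
    cents = np.asarray([c.centroid for c in clusters])
    radii = np.asarray([c.radius for c in clusters])
    labs = [c.label for c in clusters]
    # distances: n_query x n_cluster
    d = np.hypot(query_coords.points[:, None, 0] - cents[None, :, 0],
                 query_coords.points[:, None, 1] - cents[None, :, 1])
    inside = d <= radii[None, :]
    for i in range(n):
        hits = np.flatnonzero(inside[i])
        if hits.size == 0:
            continue
        if hits.size == 1:
            result[i] = labs[hits[0]]
            continue
        dists = d[i, hits]
        best = dists.min()
        tied = [labs[j] for j, dj in zip(hits, dists) if dj == best]
        result[i] = min(tied, key=str)
    return result


def validation_curve(generated_coords: Coordinates2D,
                     reference_coords: Coordinates2D,
                     labels: Sequence,
                     thresholds: Sequence[float],
                     radius_grid: RadiusGrid = RadiusGrid(),
                     density_mode: str = "area") -> pd.DataFrame:
    """Percent of generated points assigned per label and in total, per threshold.

    Refits every cluster radius at each threshold.  Long-format frame with
    columns ``density_threshold``, ``label`` (or ``"total"``) and
    ``pct_validated``; percentages are non-increasing in the threshold.
    """
    n = len(generated_coords)
    rows = []
    for thr in thresholds:
        clusters = fit_clusters(reference_coords, labels, thr, radius_grid,
                                density_mode)
        assigned = assign_labels(generated_coords, clusters)
        counts = pd.Series([a for a in assigned if a is not UNASSIGNED],
                           dtype=object).value_counts()
        total = 0
        for c in clusters:
            cnt = int(counts.get(c.label, 0))
            total += cnt
            rows.append({"density_threshold": thr, "label": c.label,
                         "pct_validated": 100.0 * cnt / n if n else 0.0})
        rows.append({"density_threshold": thr, "label": "total",
                     "pct_validated": 100.0 * total / n if n else 0.0})
    return pd.DataFrame(rows)


# -- cluster file exchange ------------------------------------------------

def export_clusters(clusters: Sequence[ClusterSpec], path) -> None:
    """CSV of (label, centroid_c1, centroid_c2, radius, density_threshold,
    n_members) — exactly what the reference holder shares for label
    assignment without releasing any reference rows."""
    pd.DataFrame([
        {"label": c.label, "centroid_c1": c.centroid[0], "centroid_c2": c.centroid[1],
         "radius": c.radius, "density_threshold": c.density_threshold,
         "n_members": c.n_members}
        for c in clusters
    ]).to_csv(path, index=False)


def import_clusters(path) -> list[ClusterSpec]:
    df = pd.read_csv(path)
    return [ClusterSpec(row["label"], (row["centroid_c1"], row["centroid_c2"]),
                        row["radius"], row["density_threshold"], int(row["n_members"]))
            for _, row in df.iterrows()]


def _as_label(x):
    """Stable label value: scalars pass through, numpy scalars unwrap."""
    return x.item() if hasattr(x, "item") else x
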