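"""Reliability scoring: band each candidate by its disparity from the local
neighborhood of the reference embedding.

For a candidate projected at point c with synthetic value x_hat, the
neighborhood mean x_bar is the arithmetic mean of the missing feature over
the k nearest reference points to c (Euclidean distance in the 2D plane).
The feature disparity f_disp = |x_hat - x_bar| is banded in multiples of a
band width epsilon, on the ORIGINAL feature scale, into a piecewise-constant
reliability score:

    f <= eps        -> 1.0         3*eps < f <= 4*eps -> 0.7
    eps < f <= 2*eps -> 0.9        4*eps < f <= 5*eps -> 0.6
    2*eps < f <= 3*eps -> 0.8      5*eps < f <= 6*eps -> 0.5
    f > 6*eps       -> 0.0  (never validated)

Candidates scoring at least r_min form the validated set D_v.  A source row
may validate several candidates — that multiplicity is the data-augmentation
half of the method and is deliberately not deduplicated here.

The module also implements both variants of the privacy-preserving two-party
exchange: either the reference holder receives candidate values and returns
scores (option 1), or it releases per-candidate neighborhood means and the
counterpart scores locally (option 2).  Both produce identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .candidate_expansion import GeneratedDataset
from .embedding import Coordinates2D

#: (multiple-of-epsilon upper bound, score), closed on the right
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 1.0), (2.0, 0.9), (3.0, 0.8), (4.0, 0.7), (5.0, 0.6), (6.0, 0.5),
)

SCORED_COLUMNS = ["row_id", "candidate_index", "x_hat", "c1", "c2",
                  "neighbor_mean", "f_disp", "r_c"]


@dataclass(frozen=True)
class ReliabilityConfig:
    """Neighbor count, band width and validation threshold.

    ``epsilon`` lives on the original feature scale (e.g. years for an age
    feature); ``score_bands`` must partition [0, inf) contiguously with
    strictly decreasing scores — anything beyond the last band scores 0.
    """

    k: int = 10
    epsilon: float = 1.0
    r_min: float = 1.0
    score_bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        uppers = [u for u, _ in self.score_bands]
        scores = [s for _, s in self.score_bands]
        if uppers != sorted(uppers) or len(set(uppers)) != len(uppers):
            raise ValueError("band upper bounds must be strictly increasing")
        if any(b >= a for a, b in zip(scores, scores[1:])):
            raise ValueError("band scores must be strictly decreasing")


def knn_mean(reference_coords: Coordinates2D,
             reference_values: Sequence[float] | np.ndarray,
             query_coords: Coordinates2D,
             k: int,
             chunk_size: int = 4096) -> np.ndarray:
    """Mean of the reference feature over each query's k nearest reference points.

    Distances are exact Euclidean distances compared as stored floats; ties
    at the k-th distance are broken by ascending reference id, making the
    result fully deterministic.  Queries are processed in chunks so the
    N_ref x N_query distance matrix never materializes at once.
    """
    values = np.asarray(reference_values, dtype=float)
    n_ref = len(reference_coords)
    if values.shape != (n_ref,):
        raise ValueError("reference_values must align with reference_coords")
    if not 1 <= k <= n_ref:
        raise ValueError(f"k={k} must be in [1, {n_ref}]")
    # order reference by ascending id; stable sorts then break ties by id
    id_order = np.argsort(np.asarray(reference_coords.ids, dtype=object), kind="stable")
    ref_pts = reference_coords.points[id_order]
    ref_vals = values[id_order]
    q = query_coords.points
    out = np.empty(len(q), dtype=float)
    for start in range(0, len(q), chunk_size):
        block = q[start:start + chunk_size]
        d = cdist(block, ref_pts)
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        out[start:start + len(block)] = ref_vals[nearest].mean(axis=1)
    return out


def score_disparity(f_disp: float | np.ndarray,
                    config: ReliabilityConfig) -> float | np.ndarray:
    """Band a disparity into its reliability score (boundaries closed right).

    Vectorized over arrays; scalar in, scalar out.
    """
    f = np.asarray(f_disp, dtype=float)
    if np.any(f < 0):
        raise ValueError("disparity must be nonnegative")
    score = np.zeros_like(f)
    assigned = np.zeros(f.shape, dtype=bool)
    for upper, s in config.score_bands:
        hit = ~assigned & (f <= upper * config.epsilon)
        score[hit] = s
        assigned |= hit
    return float(score) if np.isscalar(f_disp) else score


def score_candidates(generated: GeneratedDataset,
                     coords_g: Coordinates2D,
                     reference_coords: Coordinates2D,
                     reference_values: Sequence[float] | np.ndarray,
                     config: ReliabilityConfig) -> pd.DataFrame:
    """Score every candidate; returns one row per candidate (SCORED_COLUMNS).

    ``coords_g`` must align with the generated candidates by composite id.
    Disparity is computed on the original feature scale.
    """
    expected = generated.composite_ids()
    if list(coords_g.ids) != expected:
        raise ValueError("coords_g ids are misaligned with the generated candidates")
    means = knn_mean(reference_coords, reference_values, coords_g, config.k)
    x_hat = generated.candidates["x_hat"].to_numpy(dtype=float)
    f_disp = np.abs(x_hat - means)
    r_c = score_disparity(f_disp, config)
    return pd.DataFrame({
        "row_id": generated.candidates["row_id"].to_numpy(),
        "candidate_index": generated.candidates["candidate_index"].to_numpy(),
        "x_hat": x_hat,
        "c1": coords_g.points[:, 0],
        "c2": coords_g.points[:, 1],
        "neighbor_mean": means,
        "f_disp": f_disp,
        "r_c": r_c,
    })


def filter_validated(scored: pd.DataFrame, r_min: float) -> pd.DataFrame:
    """The validated subset D_v: candidates with r_c >= r_min and r_c > 0.

    Zero-scoring candidates never validate, so validated sets are nested as
    r_min decreases.
    """
    keep = (scored["r_c"] >= r_min) & (scored["r_c"] > 0)
    return scored.loc[keep].copy()


# -- two-party exchange (file-based, no transport) ------------------------

def exchange_score_option1(reference_coords: Coordinates2D,
                           reference_values: Sequence[float] | np.ndarray,
                           coords_g: Coordinates2D,
                           xhat_table: pd.DataFrame,
                           config: ReliabilityConfig) -> pd.DataFrame:
    """Option 1: the reference holder scores candidates it receives.

    The counterpart shares ``(id, x_hat)``; the reference holder computes the
    neighborhood means from its own embedding, bands the disparities and
    returns ``(id, r_c)``.
    """
    xhat = _aligned_xhat(xhat_table, coords_g)
    means = knn_mean(reference_coords, reference_values, coords_g, config.k)
    r_c = score_disparity(np.abs(xhat - means), config)
    return pd.DataFrame({"id": coords_g.ids, "r_c": r_c})


def exchange_neighbor_means(reference_coords: Coordinates2D,
                            reference_values: Sequence[float] | np.ndarray,
                            coords_g: Coordinates2D,
                            config: ReliabilityConfig) -> pd.DataFrame:
    """Option 2, reference side: release per-candidate neighborhood means."""
    means = knn_mean(reference_coords, reference_values, coords_g, config.k)
    return pd.DataFrame({"id": coords_g.ids, "neighbor_mean": means})


def exchange_score_option2(xhat_table: pd.DataFrame,
                           neighbor_means: pd.DataFrame,
                           config: ReliabilityConfig) -> pd.DataFrame:
    """Option 2, counterpart side: score locally from the released means.

    Produces scores identical to option 1 for the same inputs.
    """
    merged = xhat_table.merge(neighbor_means, on="id", validate="one_to_one")
    r_c = score_disparity(
        np.abs(merged["x_hat"].to_numpy(float) - merged["neighbor_mean"].to_numpy(float)),
        config)
    return pd.DataFrame({"id": merged["id"], "r_c": r_c})


def _aligned_xhat(xhat_table: pd.DataFrame, coords_g: Coordinates2D) -> np.ndarray:
    table = xhat_table.set_index(xhat_table["id"].astype(str))
    try:
        return table.loc[coords_g.ids, "x_hat"].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"x_hat table lacks id(s) present in coordinates: {exc}") from exc
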