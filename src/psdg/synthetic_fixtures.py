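"""Synthetic labeled tables with the structure the method assumes.

The generator emulates a small clinical registry: a Gaussian-mixture feature
table whose classes form separable clusters in feature (and hence embedding)
space, plus a *hidden* feature — an affine function of the latent
class-conditional position with additive Gaussian noise, clipped and rounded
to a declared range.  Because the hidden feature is tied to the latent
position, it varies smoothly across the fitted embedding, which is precisely
the regularity the neighborhood-mean validation step exploits.

Fixtures are generated at run time from (spec, seed); nothing is stored on
disk except what a caller chooses to write.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import Coordinates2D
from .tabular_core import FeatureSpec, TabularDataset


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and structure of a generated registry-like table.

    ``class_separation`` is the distance between class component means in
    units of the within-class standard deviation (default 4, comfortably
    separable).  The hidden feature is
    ``round(clip(offset + slope . latent + N(0, noise_sd)))`` where
    ``latent`` is the row's position relative to its class mean plus the
    class mean itself — i.e. an affine map of the full feature-space
    position, so neighbors in feature space carry similar hidden values.
    """

    n_rows: int = 1500
    n_features: int = 3
    n_classes: int = 2
    class_separation: float = 4.0
    hidden_name: str = "age"
    hidden_kind: str = "integer"  # integer | continuous
    hidden_range: tuple[float, float] = (35.0, 92.0)
    hidden_noise_sd: float = 1.0
    label_name: str = "label"

    def __post_init__(self):
        if not 3 <= self.n_features <= 6:
            raise ValueError("n_features must be between 3 and 6")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.hidden_kind not in ("integer", "continuous"):
            raise ValueError("hidden_kind must be integer or continuous")
        if self.hidden_range[0] >= self.hidden_range[1]:
            raise ValueError("hidden_range must be increasing")


#: plausible clinical-ish ranges for the visible (known) features
_VISIBLE_RANGES = [(0.4, 48.0),   # psa-like, ng/mL
                   (15.0, 110.0),  # volume-like, mL
                   (0.1, 3.0),    # density-like
                   (0.0, 10.0), (0.0, 10.0), (0.0, 10.0)]


def make_reference(spec: FixtureSpec, seed: int) -> TabularDataset:
    """A complete labeled table: Gaussian mixture features + smooth hidden feature.

    Reproducible byte-for-byte from (spec, seed).  The hidden feature is the
    FIRST schema column; the remaining columns are the visible features.
    """
    rng = np.random.default_rng(seed)
    n, p, c = spec.n_rows, spec.n_features, spec.n_classes
    n_visible = p - 1
    # class means on orthogonal-ish directions, separation in within-class sd units
    dirs = rng.normal(size=(c, n_visible))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    means = dirs * spec.class_separation
    labels = rng.integers(0, c, size=n)
    latent = means[labels] + rng.normal(size=(n, n_visible))

    lo, hi = spec.hidden_range
    mid, span = (lo + hi) / 2.0, (hi - lo) / 2.0
    slope = np.zeros(n_visible)
    slope[0] = 1.0  # hidden value follows the first latent axis
    z = latent @ slope
    zscale = max(np.abs(z).max(), 1e-12)
    hidden = mid + span * 0.9 * z / zscale + rng.normal(0, spec.hidden_noise_sd, n)
    hidden = np.clip(hidden, lo, hi)
    if spec.hidden_kind == "integer":
        hidden = np.rint(hidden)

    frame = pd.DataFrame(index=pd.Index([f"r{i}" for i in range(n)]))
    frame[spec.hidden_name] = hidden
    schema = [FeatureSpec(spec.hidden_name, spec.hidden_kind,
                          unit="years" if spec.hidden_kind == "integer" else "")]
    for j in range(n_visible):
        vlo, vhi = _VISIBLE_RANGES[j]
        col = latent[:, j]
        cmin, cmax = col.min(), col.max()
        scaled = vlo + (vhi - vlo) * (col - cmin) / max(cmax - cmin, 1e-12)
        name = f"f{j + 1}"
        frame[name] = scaled
        schema.append(FeatureSpec(name, "continuous"))
    frame[spec.label_name] = labels.astype(float)
    return TabularDataset(schema, frame, spec.label_name)


def make_split(spec: FixtureSpec, seed: int, reference_fraction: float = 0.2,
               drop_features: tuple[str, ...] | None = None,
               drop_label: bool = False
               ) -> tuple[TabularDataset, TabularDataset, pd.DataFrame]:
    """Disjoint (reference, incomplete, ground_truth) split of one fixture.

    The reference keeps every column; the incomplete part has the listed
    features (default: the hidden feature) and optionally the label blanked.
    ``ground_truth`` holds the blanked values, indexed by row id, so the
    original rows are exactly ``incomplete`` with the truth filled back in.
    """
    if drop_features is None:
        drop_features = (spec.hidden_name,)
    full = make_reference(spec, seed)
    rng = np.random.default_rng(seed + 1)
    n_ref = int(round(reference_fraction * full.n_rows))
    perm = rng.permutation(full.n_rows)
    ids = np.asarray(full.row_ids, dtype=object)
    ref_ids, inc_ids = ids[perm[:n_ref]], ids[perm[n_ref:]]
    reference = full.select_rows(list(ref_ids))

    inc_frame = full.frame.loc[list(inc_ids)].copy()
    truth_cols = list(drop_features) + ([spec.label_name] if drop_label else [])
    truth = inc_frame[truth_cols].copy()
    for col in drop_features:
        inc_frame[col] = np.nan
    if drop_label:
        inc_frame[spec.label_name] = np.nan
    incomplete = TabularDataset(list(full.schema), inc_frame, spec.label_name)
    return reference, incomplete, truth


def make_worked_example() -> dict:
    """A tiny hand-checkable scoring scenario covering every disparity band.

    Eight reference points sit on the x-axis at unit spacing with feature
    values 10..17; with k=1 the neighborhood mean at any reference point is
    its own value, so a candidate placed exactly on reference point i with
    x_hat = value_i + offset has disparity exactly |offset|.  The seven
    candidates use offsets 0.5, 1.5, ..., 6.5, hitting (at epsilon = 1)
    scores 1, 0.9, 0.8, 0.7, 0.6, 0.5 and 0 in order.
    """
    ref_ids = [f"p{i}" for i in range(8)]
    ref_points = np.column_stack([np.arange(8.0), np.zeros(8)])
    ref_values = np.arange(10.0, 18.0)
    offsets = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5])
    query_ids = [f"q{i}" for i in range(7)]
    query_points = ref_points[:7].copy()
    x_hat = ref_values[:7] + offsets
    expected_scores = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.0])
    return {
        "reference_coords": Coordinates2D(ref_ids, ref_points),
        "reference_values": ref_values,
        "query_coords": Coordinates2D(query_ids, query_points),
        "x_hat": x_hat,
        "offsets": offsets,
        "expected_scores": expected_scores,
        "k": 1,
        "epsilon": 1.0,
    }
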