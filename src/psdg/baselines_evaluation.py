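"""Classical imputation baselines and the rotation-validation harness.

The baselines are the two standards any practitioner reaches for first:

* **mean imputation** — every missing cell gets the reference column mean
  (snapped to the nearest grid value for non-continuous kinds);
* **k-NN imputation** — per row, the mean of the feature over the k nearest
  reference rows, with Euclidean distance measured in the *standardized
  known-feature space* (not the embedding), ties broken by reference id.

The harness evaluates the generation pipeline the only way possible without
external ground truth: split a complete table into n equal groups, hold each
group out in turn as the reference while the others play the incomplete
part with the evaluation feature blanked, and check which validated
candidates reproduce the held-out truth.  A validated candidate is *correctly
imputed* when its synthetic value equals the true value (after grid mapping);
every other validated candidate is purely synthetic.  Counts are averaged
across the n rotations.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .pipelines import PipelineConfig, run_case1
from .reliability_scoring import filter_validated
from .tabular_core import (CandidateGrid, SchemaError, TabularDataset,
                           enumerate_values, fit_normalizer, quantize_values)

R_MIN_LADDER = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def _grid_for(reference: TabularDataset, feature: str,
              quantize_levels: dict | None = None) -> CandidateGrid:
    spec = reference.feature(feature)
    if spec.kind == "continuous":
        n_levels = (quantize_levels or {}).get(feature)
        if n_levels is None:
            raise SchemaError(f"continuous feature {feature!r} needs quantize_levels")
        return quantize_values(reference, feature, n_levels)
    return enumerate_values(reference, feature)


def mean_impute(reference: TabularDataset, incomplete: TabularDataset,
                feature: str, quantize_levels: dict | None = None) -> pd.Series:
    """Reference column mean for every incomplete row (grid-snapped when discrete)."""
    value = float(reference.frame[feature].mean())
    if reference.feature(feature).kind != "continuous":
        value = _grid_for(reference, feature, quantize_levels).nearest(value)
    return pd.Series(value, index=incomplete.frame.index, name=feature)


def knn_impute(reference: TabularDataset, incomplete: TabularDataset,
               feature: str, k: int = 10,
               quantize_levels: dict | None = None) -> pd.Series:
    """Per-row k-NN mean of the feature in standardized known-feature space.

    Neighbors are found among reference rows by Euclidean distance over the
    incomplete table's known features (standardized with reference-fitted
    stats); ties at the k-th distance break by ascending reference id.
    """
    known = [n for n in incomplete.known_features if n != feature]
    if not known:
        raise SchemaError("k-NN imputation needs at least one known feature")
    if not 1 <= k <= reference.n_rows:
        raise ValueError(f"k={k} must be in [1, {reference.n_rows}]")
    stats = fit_normalizer(reference)
    ref_ids = np.asarray(reference.row_ids, dtype=object)
    order = np.argsort(ref_ids, kind="stable")
    X_ref = stats.transform(reference.feature_matrix(known), known)[order]
    vals = reference.frame[feature].to_numpy(float)[order]
    X_q = stats.transform(incomplete.feature_matrix(known), known)
    out = np.empty(len(X_q))
    for start in range(0, len(X_q), 4096):
        block = X_q[start:start + 4096]
        d = cdist(block, X_ref)
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        out[start:start + len(block)] = vals[nearest].mean(axis=1)
    if reference.feature(feature).kind != "continuous":
        grid = _grid_for(reference, feature, quantize_levels)
        out = np.asarray([grid.nearest(v) for v in out])
    return pd.Series(out, index=incomplete.frame.index, name=feature)


@dataclass
class EvaluationReport:
    """Rotation-harness results.

    ``counts`` is long-format, one row per (rotation, method, r_min) with
    columns ``validated``, ``correctly_imputed``, ``synthetic`` and
    ``n_incomplete`` (baselines carry r_min = NaN and validated = number of
    imputed rows).  ``per_value`` records, per (method, r_min, true value),
    how many rows were correctly imputed and how many truths exist, for
    range tables.
    """

    counts: pd.DataFrame
    per_value: pd.DataFrame
    n_groups: int
    group_size: int
    feature: str

    def mean_counts(self) -> pd.DataFrame:
        """Counts averaged across rotations, per (method, r_min)."""
        return (self.counts
                .groupby(["method", "r_min"], dropna=False)
                [["validated", "correctly_imputed", "synthetic", "n_incomplete"]]
                .mean().reset_index())

    def correct_percentage(self, method: str, r_min: float | None = None) -> float:
        """Mean % of incomplete rows correctly imputed by a method."""
        df = self.counts[self.counts["method"] == method]
        if r_min is not None:
            df = df[df["r_min"] == r_min]
        if df.empty:
            raise KeyError(f"no rows for method={method!r}, r_min={r_min}")
        return float((100.0 * df["correctly_imputed"] / df["n_incomplete"]).mean())


def rotation_validate(complete: TabularDataset, n_groups: int, feature: str,
                      config: PipelineConfig,
                      r_min_ladder: Sequence[float] = R_MIN_LADDER,
                      baseline_k: int = 10) -> EvaluationReport:
    """Hold each of ``n_groups`` equal groups out as the reference in turn.

    The complete table is shuffled with the config seed and cut into equal
    groups (remainder rows dropped with a warning).  Each rotation scores the
    full candidate set once and counts validated / correctly-imputed /
    synthetic candidates down the r_min ladder, plus both baselines.
    """
    rng = np.random.default_rng(config.seed)
    ids = np.asarray(complete.row_ids, dtype=object)
    perm = rng.permutation(len(ids))
    group_size = len(ids) // n_groups
    if group_size * n_groups < len(ids):
        warnings.warn(f"dropping {len(ids) - group_size * n_groups} remainder rows "
                      f"to form {n_groups} equal groups of {group_size}")
    groups = [ids[perm[g * group_size:(g + 1) * group_size]] for g in range(n_groups)]

    count_rows, value_rows = [], []
    ladder = sorted(r_min_ladder)
    for g, ref_ids in enumerate(groups):
        reference = complete.select_rows(list(ref_ids))
        inc_ids = np.concatenate([groups[h] for h in range(n_groups) if h != g])
        inc_frame = complete.frame.loc[list(inc_ids)].copy()
        truth = inc_frame[feature].copy()
        inc_frame[feature] = np.nan
        incomplete = TabularDataset(list(complete.schema), inc_frame,
                                    complete.label_name)

        grid = _grid_for(reference, feature, config.quantize_levels)
        truth_grid = truth.map(grid.nearest)

        scored_cfg = dataclasses.replace(config, r_min=min(ladder))
        result = run_case1(reference, incomplete, scored_cfg)
        scored = result.rows
        truth_of = truth_grid.to_dict()
        is_correct = scored["x_hat"].to_numpy() == \
            scored["row_id"].map(truth_of).to_numpy()
        for r_min in ladder:
            v = filter_validated(scored, r_min)
            correct_mask = is_correct[scored.index.get_indexer(v.index)]
            n_corr = int(correct_mask.sum())
            count_rows.append({"rotation": g, "method": "psdg", "r_min": r_min,
                               "validated": len(v), "correctly_imputed": n_corr,
                               "synthetic": len(v) - n_corr,
                               "n_incomplete": incomplete.n_rows})
            corr_rows = v.loc[correct_mask, "row_id"]
            per_val = truth_grid.loc[corr_rows].value_counts()
            for true_val, cnt in truth_grid.value_counts().items():
                value_rows.append({"rotation": g, "method": "psdg", "r_min": r_min,
                                   "true_value": true_val, "n_true": int(cnt),
                                   "n_correct": int(per_val.get(true_val, 0))})

        for method, imputed in (
                ("mean", mean_impute(reference, incomplete, feature,
                                     config.quantize_levels)),
                ("knn", knn_impute(reference, incomplete, feature, baseline_k,
                                   config.quantize_levels))):
            ok = imputed.to_numpy() == truth_grid.to_numpy()
            count_rows.append({"rotation": g, "method": method, "r_min": np.nan,
                               "validated": len(imputed),
                               "correctly_imputed": int(ok.sum()),
                               "synthetic": int(len(imputed) - ok.sum()),
                               "n_incomplete": incomplete.n_rows})
            per_val = truth_grid[ok].value_counts()
            for true_val, cnt in truth_grid.value_counts().items():
                value_rows.append({"rotation": g, "method": method, "r_min": np.nan,
                                   "true_value": true_val, "n_true": int(cnt),
                                   "n_correct": int(per_val.get(true_val, 0))})

    return EvaluationReport(pd.DataFrame(count_rows), pd.DataFrame(value_rows),
                            n_groups, group_size, feature)


def range_table(report: EvaluationReport,
                bin_edges: Sequence[float]) -> pd.DataFrame:
    """Per-range correct-imputation percentages, one row per method x r_min.

    Bins are ``[e0, e1], (e1, e2], ...`` over the true values; a range with no
    true rows is blank (NaN), not 0.  A trailing ``mean_pct`` column averages
    the defined ranges.
    """
    edges = list(bin_edges)
    labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]
    pv = report.per_value.copy()
    pv["bin"] = pd.cut(pv["true_value"], bins=edges, labels=labels,
                       include_lowest=True)
    rows = []
    for (method, r_min), grp in pv.groupby(["method", "r_min"], dropna=False):
        agg = grp.groupby("bin", observed=False)[["n_correct", "n_true"]].sum()
        row = {"method": method, "r_min": r_min}
        pcts = []
        for lab in labels:
            n_true = agg.loc[lab, "n_true"] if lab in agg.index else 0
            if n_true == 0:
                row[lab] = np.nan
            else:
                pct = 100.0 * agg.loc[lab, "n_correct"] / n_true
                row[lab] = pct
                pcts.append(pct)
        row["mean_pct"] = float(np.mean(pcts)) if pcts else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def render_range_table(table: pd.DataFrame) -> str:
    """Fixed-width text rendering of a range table."""
    out = table.copy()
    for col in out.columns:
        if col not in ("method", "r_min"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    return out.to_string(index=False)
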