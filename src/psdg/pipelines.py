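"""Pipelines: the composed run modes of the generation/imputation framework.

Three single-pass cases, after the two-institution scenario they serve:

* **case 1** — label known, one feature missing: expand candidates, embed,
  score, keep candidates with reliability >= r_min (partial synthesis; the
  known features of every output row are bit-equal to their source row).
* **case 0** — all features known, label missing: project rows and assign
  labels through per-class cluster areas; unassigned rows are dropped.
* **case 2** — feature and label both missing: reliability filter first, then
  cluster assignment of the survivors.

Two derived modes:

* **full synthesis** — apply case 1 (or case 2 when the label is missing)
  iteratively, one feature at a time; each round adds the newly generated
  attribute to the reference feature set so the next embedding sees it.
* **imputation** — partition a mixed-missingness table by missing pattern,
  run case 1 per single-feature pattern, and keep exactly one value per
  missing cell: the validated candidate with the highest score (ties to the
  smallest disparity, then the smallest value).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .candidate_expansion import expand, materialize
from .cluster_validation import (RadiusGrid, assign_labels, fit_clusters)
from .embedding import (Coordinates2D, EmbeddingHyperparameters, EmbeddingModel,
                        fit_embedding, project)
from .reliability_scoring import (ReliabilityConfig, filter_validated,
                                  score_candidates)
from .tabular_core import (CandidateGrid, SchemaError, TabularDataset,
                           align_schemas, enumerate_values, quantize_values)

MODES = ("case0", "case1", "case2", "full_synthesis", "imputation")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs besides the two datasets; the seed is mandatory."""

    seed: int
    mode: str = "case1"
    embedding: EmbeddingHyperparameters = field(default_factory=EmbeddingHyperparameters)
    k: int = 10
    epsilon: float | None = None  # None -> the grid's default band width
    r_min: float = 1.0
    density_threshold: float = 1.0
    radius_grid: RadiusGrid = field(default_factory=RadiusGrid)
    density_mode: str = "area"
    quantize_levels: dict = field(default_factory=dict)  # feature -> n_levels
    feature_order: tuple[str, ...] | None = None  # iterative modes
    chunk_size: int | None = None
    strict_epsilon: bool = False  # force epsilon on binary/categorical too

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def config_hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "mode": self.mode,
            "embedding": [self.embedding.n_neighbors, self.embedding.min_dist,
                          self.embedding.metric],
            "k": self.k, "epsilon": self.epsilon, "r_min": self.r_min,
            "density_threshold": self.density_threshold,
            "radius_grid": [self.radius_grid.r_start, self.radius_grid.r_step,
                            self.radius_grid.r_max],
            "density_mode": self.density_mode,
            "quantize_levels": sorted(self.quantize_levels.items()),
            "feature_order": self.feature_order,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def reliability(self, grid: CandidateGrid) -> ReliabilityConfig:
        eps = self.epsilon if self.epsilon is not None else grid.epsilon_default
        return ReliabilityConfig(k=self.k, epsilon=eps, r_min=self.r_min)


@dataclass
class ValidatedDataset:
    """Validated candidates with full provenance.

    ``rows`` carries the source row's known features, the synthetic value(s),
    2D coordinates, neighborhood mean, disparity and score, plus the assigned
    label where cluster validation ran.
    """

    rows: pd.DataFrame
    feature_name: str | None
    config_hash: str
    counts: dict

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# psdg validated dataset; config_hash={self.config_hash}; "
                     f"counts={json.dumps(self.counts, sort_keys=True)}\n")
            self.rows.to_csv(fh, index=False)


def make_grid(reference: TabularDataset, feature: str,
              config: PipelineConfig) -> CandidateGrid:
    """Enumerate or quantize the candidate grid per the feature kind."""
    if reference.feature(feature).kind == "continuous":
        n_levels = config.quantize_levels.get(feature)
        if n_levels is None:
            raise SchemaError(
                f"continuous feature {feature!r} needs quantize_levels in the config")
        return quantize_values(reference, feature, n_levels)
    return enumerate_values(reference, feature)


def _score_stage(reference: TabularDataset, incomplete: TabularDataset,
                 config: PipelineConfig,
                 model: EmbeddingModel | None = None):
    """Shared steps 1-4: align, grid, expand, embed, project, score."""
    reference, incomplete = align_schemas(reference, incomplete)
    feature = incomplete.unknown_features[0]
    grid = make_grid(reference, feature, config)
    generated = expand(incomplete, grid)
    if model is None:
        model = fit_embedding(reference, config.embedding, config.seed)
    candidates = materialize(generated, config.chunk_size)
    coords_g = project(model, candidates)
    ref_coords = model.training_coords
    ref_values = reference.frame.loc[ref_coords.ids, feature].to_numpy(float)
    scored = score_candidates(generated, coords_g, ref_coords, ref_values,
                              config.reliability(grid))
    return reference, incomplete, feature, grid, model, scored


def _attach_known(validated: pd.DataFrame, incomplete: TabularDataset,
                  feature: str) -> pd.DataFrame:
    """Join source-row known features (bit-equal) onto validated candidates."""
    known = incomplete.frame.drop(columns=[feature])
    out = validated.merge(known, left_on="row_id", right_index=True, how="left")
    return out


def run_case1(reference: TabularDataset, incomplete: TabularDataset,
              config: PipelineConfig) -> ValidatedDataset:
    """Partial synthesis: generate and validate values for one missing feature."""
    if len(incomplete.unknown_features) != 1:
        raise SchemaError("case 1 requires exactly one missing feature")
    reference, incomplete, feature, grid, model, scored = _score_stage(
        reference, incomplete, config)
    validated = filter_validated(scored, config.r_min)
    rows = _attach_known(validated, incomplete, feature)
    counts = {"N_r": reference.n_rows, "N_i": incomplete.n_rows, "M": grid.M,
              "D_g": len(scored), "D_v": len(validated)}
    return ValidatedDataset(rows, feature, config.config_hash(), counts)


def run_case0(reference: TabularDataset, incomplete: TabularDataset,
              config: PipelineConfig) -> ValidatedDataset:
    """Label assignment: project complete rows and label them via cluster areas."""
    if incomplete.unknown_features:
        raise SchemaError("case 0 requires all features known")
    if reference.labels is None:
        raise SchemaError("case 0 requires a labeled reference")
    reference, incomplete = align_schemas(reference, incomplete)
    model = fit_embedding(reference, config.embedding, config.seed)
    coords = project(model, incomplete)
    clusters = fit_clusters(model.training_coords,
                            reference.labels.loc[model.training_coords.ids],
                            config.density_threshold, config.radius_grid,
                            config.density_mode)
    labels = assign_labels(coords, clusters)
    keep = [i for i, lab in enumerate(labels) if lab is not None]
    frame = incomplete.frame.iloc[keep].copy()
    frame["y_hat"] = [labels[i] for i in keep]
    frame["c1"] = coords.points[keep, 0]
    frame["c2"] = coords.points[keep, 1]
    frame.insert(0, "row_id", frame.index)
    counts = {"N_r": reference.n_rows, "N_i": incomplete.n_rows,
              "assigned": len(keep), "unassigned": incomplete.n_rows - len(keep)}
    return ValidatedDataset(frame.reset_index(drop=True), None,
                            config.config_hash(), counts)


def run_case2(reference: TabularDataset, incomplete: TabularDataset,
              config: PipelineConfig) -> ValidatedDataset:
    """Feature and label both missing: reliability filter, then cluster areas.

    The output is the case-1 output restricted to candidates whose projected
    point falls inside a class area, with the assigned label attached.
    """
    if reference.labels is None:
        raise SchemaError("case 2 requires a labeled reference")
    reference, incomplete, feature, grid, model, scored = _score_stage(
        reference, incomplete, config)
    validated = filter_validated(scored, config.r_min)
    clusters = fit_clusters(model.training_coords,
                            reference.labels.loc[model.training_coords.ids],
                            config.density_threshold, config.radius_grid,
                            config.density_mode)
    coords_v = Coordinates2D(
        [f"{r}#{c}" for r, c in zip(validated["row_id"], validated["candidate_index"])],
        validated[["c1", "c2"]].to_numpy(float)) if len(validated) else None
    if coords_v is not None:
        labels = assign_labels(coords_v, clusters)
        keep = [i for i, lab in enumerate(labels) if lab is not None]
        survivors = validated.iloc[keep].copy()
        survivors["y_hat"] = [labels[i] for i in keep]
    else:
        survivors = validated.copy()
        survivors["y_hat"] = []
    rows = _attach_known(survivors, incomplete, feature)
    counts = {"N_r": reference.n_rows, "N_i": incomplete.n_rows, "M": grid.M,
              "D_g": len(scored), "D_v_reliability": len(validated),
              "D_v": len(survivors)}
    return ValidatedDataset(rows, feature, config.config_hash(), counts)


def default_feature_order(reference: TabularDataset,
                          candidates: Sequence[str]) -> list[str]:
    """Features to generate, by descending |correlation with the label|."""
    if reference.labels is None:
        raise SchemaError("feature ordering by label correlation needs a label")
    y = reference.labels.to_numpy(float)
    corrs = {}
    for name in candidates:
        x = reference.frame[name].to_numpy(float)
        sx, sy = x.std(), y.std()
        corrs[name] = abs(float(np.corrcoef(x, y)[0, 1])) if sx > 0 and sy > 0 else 0.0
    return sorted(candidates, key=lambda n: (-corrs[n], n))


def run_full_synthesis(reference: TabularDataset, incomplete: TabularDataset,
                       config: PipelineConfig) -> ValidatedDataset:
    """Iteratively synthesize every missing feature, one per round.

    Round t treats previously generated features as known: the working table
    (which may have grown, since several candidates of one row can validate)
    becomes the next round's incomplete input, and the reference restricted
    to known-so-far + the next feature drives a fresh embedding, grid and —
    when the label is missing — fresh cluster radii.  An empty feature order
    is the identity.
    """
    order = list(config.feature_order) if config.feature_order is not None else \
        default_feature_order(reference, incomplete.unknown_features)
    for name in order:
        if name not in reference.feature_names:
            raise SchemaError(f"feature {name!r} in feature_order absent from reference")

    label_missing = incomplete.has_missing_label and reference.labels is not None
    work = incomplete
    iteration_counts = []
    rows_out = None
    for feature in order:
        known = [n for n in work.known_features]
        sub_schema = [reference.feature(n) for n in known] + [reference.feature(feature)]
        ref_cols = known + [feature] + ([reference.label_name] if reference.label_name else [])
        sub_ref = TabularDataset(sub_schema, reference.frame[ref_cols],
                                 reference.label_name)
        inc_cols = known + [feature] + ([work.label_name] if work.label_name else [])
        inc_frame = work.frame.copy()
        inc_frame[feature] = np.nan
        sub_inc = TabularDataset(sub_schema, inc_frame[inc_cols], work.label_name,
                                 allow_partial_missing=True)
        step = run_case2(sub_ref, sub_inc, config) if label_missing else \
            run_case1(sub_ref, sub_inc, config)
        iteration_counts.append({"feature": feature, **step.counts})
        # rebuild the working table: validated rows with the new feature known
        new_frame = step.rows.copy()
        new_frame[feature] = new_frame["x_hat"]
        if label_missing and "y_hat" in new_frame:
            new_frame[work.label_name] = new_frame["y_hat"]
        new_frame.index = pd.Index(
            [f"{r}#{c}" for r, c in zip(new_frame["row_id"],
                                        new_frame["candidate_index"])])
        cols = known + [feature] + ([work.label_name] if work.label_name else [])
        work = TabularDataset(sub_schema, new_frame[cols], work.label_name,
                              allow_partial_missing=True)
        rows_out = new_frame
    if rows_out is None:  # empty order: identity
        rows_out = incomplete.frame.copy()
        rows_out.insert(0, "row_id", rows_out.index)
    counts = {"iterations": iteration_counts, "N_i": incomplete.n_rows,
              "final_rows": len(work.frame) if order else incomplete.n_rows}
    return ValidatedDataset(rows_out.reset_index(drop=True),
                            order[-1] if order else None,
                            config.config_hash(), counts)


def run_imputation(incomplete: TabularDataset, reference: TabularDataset,
                   config: PipelineConfig, top_n: int = 1
                   ) -> tuple[TabularDataset, pd.DataFrame]:
    """Fill one value per missing cell from the validated candidates.

    Rows are partitioned by missing-feature pattern; each single-feature
    pattern runs the partial-synthesis pipeline against the reference, and
    each missing cell takes its best validated candidate (highest score, then
    smallest disparity, then smallest value).  Returns the imputed table and
    a report of cells that stayed missing (no validated candidate, or a
    pattern with several missing features).  ``top_n > 1`` returns the top-n
    candidates per cell in the report instead of only the winner, for
    multiple-imputation style use.
    """
    frame = incomplete.frame.copy()
    feat_names = incomplete.feature_names
    na = frame[feat_names].isna()
    patterns = na.apply(lambda row: tuple(c for c in feat_names if row[c]), axis=1)
    report_rows = []
    for pattern, idx in patterns.groupby(patterns).groups.items():
        if len(pattern) == 0:
            continue
        if len(pattern) > 1:
            for rid in idx:
                for feat in pattern:
                    report_rows.append({"row_id": rid, "feature": feat,
                                        "status": "multi_missing", "x_hat": np.nan,
                                        "r_c": np.nan, "rank": np.nan})
            continue
        feature = pattern[0]
        sub = TabularDataset(list(incomplete.schema), frame.loc[list(idx)],
                             incomplete.label_name, allow_partial_missing=True)
        result = run_case1(reference, sub, config)
        v = result.rows
        filled_ids = set()
        if len(v):
            v = v.sort_values(["r_c", "f_disp", "x_hat"],
                              ascending=[False, True, True], kind="stable")
            for rid, grp in v.groupby("row_id", sort=False):
                best = grp.iloc[0]
                frame.loc[rid, feature] = best["x_hat"]
                filled_ids.add(rid)
                for rank, (_, cand) in enumerate(grp.head(top_n).iterrows(), start=1):
                    report_rows.append({"row_id": rid, "feature": feature,
                                        "status": "imputed", "x_hat": cand["x_hat"],
                                        "r_c": cand["r_c"], "rank": rank})
        for rid in idx:
            if rid not in filled_ids:
                report_rows.append({"row_id": rid, "feature": feature,
                                    "status": "unimputed", "x_hat": np.nan,
                                    "r_c": np.nan, "rank": np.nan})
    imputed = TabularDataset(list(incomplete.schema), frame, incomplete.label_name,
                             allow_partial_missing=True)
    report = pd.DataFrame(report_rows,
                          columns=["row_id", "feature", "status", "x_hat",
                                   "r_c", "rank"])
    return imputed, report
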