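"""Tabular data model: typed schemas, CSV I/O, alignment, scaling, candidate grids.

The central object is :class:`TabularDataset`, a thin typed wrapper around a
pandas DataFrame that distinguishes *known* feature columns from *unknown*
ones.  An unknown feature is one that is missing in **every** row — the
uniform-missingness setting of partially synthetic data generation, where a
whole attribute (e.g. patient age) is absent from one institution's records.
A *reference* dataset has no unknown features; an *incomplete* dataset has at
least one.

Candidate grids enumerate the finite set of values a missing feature can
take: discrete kinds are enumerated from the reference, continuous kinds are
quantized into uniform bins whose midpoints form the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Feature kinds with a finite, ordered set of admissible encoded values.
DISCRETE_KINDS = ("integer", "ordinal", "categorical", "binary")
KINDS = ("continuous",) + DISCRETE_KINDS


class SchemaError(ValueError):
    """Raised when a table does not conform to its declared schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single feature: its kind, unit and admissible levels.

    Parameters
    ----------
    name : str
        Column identifier.
    kind : str
        One of ``continuous``, ``integer``, ``ordinal``, ``categorical``,
        ``binary``.  Non-continuous kinds are encoded numerically.
    unit : str
        Free-text unit (e.g. ``"ng/mL"``); used for cross-dataset alignment.
    levels : tuple of float, optional
        Ordered admissible encoded values; required for ``ordinal``,
        ``categorical`` and ``binary``, optional for ``integer``.
    """

    name: str
    kind: str
    unit: str = ""
    levels: tuple | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            if self.levels is not None:
                raise SchemaError(f"continuous feature {self.name!r} must not declare levels")
        elif self.kind in ("ordinal", "categorical", "binary"):
            if not self.levels:
                raise SchemaError(f"{self.kind} feature {self.name!r} requires levels")
        if self.levels is not None:
            lv = tuple(float(v) for v in self.levels)
            if len(set(lv)) != len(lv):
                raise SchemaError(f"duplicate levels for {self.name!r}")
            if self.kind in ("integer", "ordinal") and list(lv) != sorted(lv):
                raise SchemaError(f"levels of ordered feature {self.name!r} must be sorted")
            object.__setattr__(self, "levels", lv)


def _schema_names(schema: Sequence[FeatureSpec]) -> list[str]:
    names = [f.name for f in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate feature names in schema")
    return names


@dataclass
class TabularDataset:
    """Rows x typed features with an optional label column and a known/unknown split.

    ``frame`` is indexed by stable string row ids and holds one column per
    schema feature (float dtype, NaN = missing) plus, optionally, the label
    column.  A feature is *unknown* when it is missing in every row; in
    strict mode (the default) a feature that is missing in only some rows is
    rejected — such mixed patterns belong to the imputation pipeline, which
    partitions rows by missingness pattern first.
    """

    schema: list[FeatureSpec]
    frame: pd.DataFrame
    label_name: str | None = None
    allow_partial_missing: bool = False

    def __post_init__(self):
        names = _schema_names(self.schema)
        expected = names + ([self.label_name] if self.label_name else [])
        missing = [c for c in expected if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"frame lacks columns {missing}")
        extra = [c for c in self.frame.columns if c not in expected]
        if extra:
            raise SchemaError(f"frame has undeclared columns {extra}")
        self.frame = self.frame[expected].copy()
        self.frame.index = self.frame.index.astype(str)
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise SchemaError(f"duplicate row_ids {dupes[:5]}")
        for f in self.schema:
            self.frame[f.name] = pd.to_numeric(self.frame[f.name], errors="raise")
        if not self.allow_partial_missing:
            for f in self.schema:
                n_na = int(self.frame[f.name].isna().sum())
                if 0 < n_na < len(self.frame):
                    raise SchemaError(
                        f"feature {f.name!r} is missing in {n_na}/{len(self.frame)} rows; "
                        "uniform missingness required (use the imputation pipeline "
                        "for mixed missingness patterns)"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.schema]

    @property
    def known_mask(self) -> dict[str, bool]:
        return {f.name: not self.frame[f.name].isna().all() for f in self.schema}

    @property
    def known_features(self) -> list[str]:
        km = self.known_mask
        return [n for n in self.feature_names if km[n]]

    @property
    def unknown_features(self) -> list[str]:
        km = self.known_mask
        return [n for n in self.feature_names if not km[n]]

    @property
    def d(self) -> int:
        return len(self.schema)

    @property
    def d_K(self) -> int:
        return len(self.known_features)

    @property
    def d_U(self) -> int:
        return self.d - self.d_K

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def is_reference(self) -> bool:
        return self.d_U == 0

    @property
    def has_missing_label(self) -> bool:
        if self.label_name is None:
            return True
        return bool(self.frame[self.label_name].isna().all())

    @property
    def labels(self) -> pd.Series | None:
        if self.label_name is None:
            return None
        return self.frame[self.label_name]

    def feature(self, name: str) -> FeatureSpec:
        for f in self.schema:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Feature values (label excluded) as a float array in the given order."""
        cols = list(order) if order is not None else self.feature_names
        return self.frame[cols].to_numpy(dtype=float)

    def with_frame(self, frame: pd.DataFrame) -> "TabularDataset":
        return TabularDataset(list(self.schema), frame, self.label_name,
                              self.allow_partial_missing)

    def select_rows(self, row_ids: Sequence[str]) -> "TabularDataset":
        return self.with_frame(self.frame.loc[list(row_ids)])

    def write_csv(self, path) -> None:
        """Write rows as CSV (row_id column first, empty string = missing)."""
        out = self.frame.copy()
        out.insert(0, "row_id", out.index)
        out.to_csv(path, index=False, na_rep="")


# -- schema sidecar ------------------------------------------------------

def load_schema(path) -> tuple[list[FeatureSpec], str | None]:
    """Read a YAML/JSON sidecar declaring feature kinds, units, levels and label.

    Layout::

        features:
          - {name: age, kind: integer}
          - {name: psa, kind: continuous, unit: "ng/mL"}
        label: case_csPCA
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    feats = [
        FeatureSpec(
            name=f["name"], kind=f["kind"], unit=f.get("unit", ""),
            levels=tuple(f["levels"]) if f.get("levels") is not None else None,
        )
        for f in doc["features"]
    ]
    return feats, doc.get("label")


def save_schema(schema: Sequence[FeatureSpec], label_name: str | None, path) -> None:
    doc = {
        "features": [
            {k: v for k, v in
             dict(name=f.name, kind=f.kind, unit=f.unit,
                  levels=list(f.levels) if f.levels else None).items()
             if v not in ("", None)}
            for f in schema
        ],
        "label": label_name,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_table(path, schema: Sequence[FeatureSpec], label_name: str | None = None,
               strict: bool = True) -> TabularDataset:
    """Read a CSV into a :class:`TabularDataset`.

    The header must contain every schema feature (plus the label column when
    declared); an optional leading ``row_id`` column supplies stable ids,
    otherwise ids are the 0-based row positions.  Empty cells become the
    missing marker.  With ``strict=True`` a feature missing in only some rows
    is rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = _schema_names(list(schema))
    expected = set(names) | ({label_name} if label_name else set())
    present = set(df.columns) - {"row_id"}
    unknown = present - expected
    if unknown:
        raise SchemaError(f"unknown column(s) {sorted(unknown)} in {path}")
    absent = expected - present
    if absent:
        raise SchemaError(f"column(s) {sorted(absent)} absent from {path}")
    if "row_id" in df.columns:
        df = df.set_index("row_id")
    else:
        df.index = pd.Index([str(i) for i in range(len(df))])
    df = df.replace("", np.nan)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(f"unparseable cell at row {row!r}, column {col!r}") from exc
    return TabularDataset(list(schema), df, label_name,
                          allow_partial_missing=not strict)


# -- schema alignment ----------------------------------------------------

def align_schemas(reference: TabularDataset, incomplete: TabularDataset,
                  unit_equivalences: Iterable[tuple[str, str]] = ()
                  ) -> tuple[TabularDataset, TabularDataset]:
    """Check that the incomplete dataset's known features match the reference
    and reorder both known-first.

    Every known feature of ``incomplete`` must exist in ``reference`` with the
    same kind and a compatible unit.  Units differing only by a declared
    equivalence pair (e.g. ``("cc", "mL")``) are accepted.  Returns the pair
    with feature columns permuted so known features precede unknown ones.
    """
    equiv = {frozenset(p) for p in unit_equivalences}

    def units_ok(a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in equiv

    ref_by_name = {f.name: f for f in reference.schema}
    common = []
    for f in incomplete.schema:
        if not incomplete.known_mask[f.name]:
            continue
        rf = ref_by_name.get(f.name)
        if rf is None:
            raise SchemaError(f"known feature {f.name!r} absent from reference")
        if rf.kind != f.kind:
            raise SchemaError(f"kind mismatch for {f.name!r}: {rf.kind} vs {f.kind}")
        if not units_ok(rf.unit, f.unit):
            raise SchemaError(
                f"unit mismatch for {f.name!r}: {rf.unit!r} vs {f.unit!r} "
                "(declare an equivalence to accept)")
        common.append(f.name)
    if not common:
        raise SchemaError("no common known features between reference and incomplete")

    def reorder(ds: TabularDataset) -> TabularDataset:
        order = ds.known_features + ds.unknown_features
        schema = [ds.feature(n) for n in order]
        cols = order + ([ds.label_name] if ds.label_name else [])
        return TabularDataset(schema, ds.frame[cols], ds.label_name,
                              ds.allow_partial_missing)

    return reorder(reference), reorder(incomplete)


# -- normalization -------------------------------------------------------

@dataclass(frozen=True)
class NormalizerStats:
    """Per-feature standard-scaling statistics fitted on a reference dataset.

    Location is the sample mean and scale the population (divide-by-N)
    standard deviation, so transforming the fitting reference yields columns
    with mean 0 and unit sd.
    """

    feature_names: tuple[str, ...]
    location: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
        idx = self._indices(names)
        return (values - self.location[idx]) / self.scale[idx]

    def inverse(self, values: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
        idx = self._indices(names)
        return values * self.scale[idx] + self.location[idx]

    def _indices(self, names: Sequence[str] | None) -> np.ndarray:
        if names is None:
            return np.arange(len(self.feature_names))
        pos = {n: i for i, n in enumerate(self.feature_names)}
        try:
            return np.array([pos[n] for n in names], dtype=int)
        except KeyError as exc:
            raise SchemaError(f"feature {exc.args[0]!r} absent from normalizer") from exc


def fit_normalizer(reference: TabularDataset) -> NormalizerStats:
    """Fit standard-scaling stats on a complete reference (label excluded)."""
    if reference.d_U:
        raise SchemaError("normalizer must be fitted on a complete reference (d_U = 0)")
    X = reference.feature_matrix()
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    for name, s in zip(reference.feature_names, scale):
        if s <= 0:
            raise SchemaError(f"constant column {name!r}: cannot standardize")
    return NormalizerStats(tuple(reference.feature_names), loc, scale)


def apply_normalizer(stats: NormalizerStats, dataset: TabularDataset) -> TabularDataset:
    """Return a standardized copy; missing markers pass through unchanged."""
    out = dataset.frame.copy()
    for name in dataset.feature_names:
        col = out[name].to_numpy(dtype=float)
        out[name] = stats.transform(col, [name])
    return dataset.with_frame(out)


# -- candidate grids -----------------------------------------------------

@dataclass(frozen=True)
class CandidateGrid:
    """The finite, sorted set of M candidate values for one missing feature.

    ``epsilon_default`` is the suggested disparity band width on the original
    feature scale: 1 for integer/ordinal kinds, half the minimum level gap
    for categorical/binary, and the bin width for quantized continuous
    features.
    """

    feature_name: str
    values: tuple
    epsilon_default: float
    origin: str  # "enumerated" | "quantized"

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("candidate grid must have at least one value")
        if len(set(vals)) != len(vals):
            raise ValueError("candidate grid values must be duplicate-free")
        if list(vals) != sorted(vals):
            raise ValueError("candidate grid values must be sorted")
        object.__setattr__(self, "values", vals)

    @property
    def M(self) -> int:
        return len(self.values)

    def nearest(self, x: float) -> float:
        """Grid value nearest to ``x`` (ties toward the smaller value)."""
        arr = np.asarray(self.values)
        return float(arr[int(np.argmin(np.abs(arr - x)))])


def enumerate_values(reference: TabularDataset, feature: str) -> CandidateGrid:
    """Enumerate the candidate grid of a non-continuous feature.

    Integer features span every integer of the closed observed range (ages
    35–92 give M = 58 regardless of interior gaps); level-bearing kinds use
    their declared levels.  epsilon defaults to 1 for ordered kinds and half
    the minimum level gap otherwise.
    """
    spec = reference.feature(feature)
    if spec.kind == "continuous":
        raise SchemaError(f"{feature!r} is continuous; use quantize_values")
    col = reference.frame[feature].dropna().to_numpy(dtype=float)
    if col.size == 0:
        raise SchemaError(f"feature {feature!r} has no observed values in reference")
    if spec.kind == "integer":
        lo, hi = int(np.min(col)), int(np.max(col))
        values = tuple(float(v) for v in range(lo, hi + 1))
        eps = 1.0
    else:
        values = spec.levels
        eps = 1.0 if spec.kind == "ordinal" else _half_min_gap(values)
    return CandidateGrid(feature, values, eps, "enumerated")


def _half_min_gap(values: Sequence[float]) -> float:
    vals = sorted(values)
    if len(vals) < 2:
        return 1.0
    return min(b - a for a, b in zip(vals, vals[1:])) / 2.0


def quantize_values(reference: TabularDataset, feature: str, n_levels: int) -> CandidateGrid:
    """Quantize a continuous feature into ``n_levels`` uniform bins.

    The grid holds the bin midpoints over the reference [min, max];
    epsilon defaults to the bin width.
    """
    spec = reference.feature(feature)
    if spec.kind != "continuous":
        raise SchemaError(f"{feature!r} is not continuous; use enumerate_values")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    col = reference.frame[feature].dropna().to_numpy(dtype=float)
    lo, hi = float(np.min(col)), float(np.max(col))
    if lo == hi:
        if n_levels > 1:
            raise SchemaError(f"degenerate range for {feature!r}: min == max == {lo}")
        return CandidateGrid(feature, (lo,), 1.0, "quantized")
    width = (hi - lo) / n_levels
    mids = tuple(lo + width * (i + 0.5) for i in range(n_levels))
    return CandidateGrid(feature, mids, width, "quantized")
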