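"""Candidate expansion: build the generated dataset D_g = D_i x grid.

Every incomplete row is replicated once per candidate value of the missing
feature, so |D_g| = N_i * M exactly.  Ordering is deterministic (row-major by
source row, ascending candidate value) and expansion can be consumed in
chunks without changing the result, which keeps the 10^6-row expansions of
large registries memory-safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .tabular_core import CandidateGrid, SchemaError, TabularDataset

#: separator between source row id and candidate index in composite ids
ID_SEP = "#"


@dataclass
class GeneratedDataset:
    """The Cartesian expansion of an incomplete table over a candidate grid.

    ``candidates`` has one row per (source row, candidate) pair with columns
    ``row_id``, ``candidate_index`` and ``x_hat``; known features live in
    ``base`` and are joined in on materialization.
    """

    base: TabularDataset
    feature_name: str
    candidates: pd.DataFrame
    provenance: CandidateGrid

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def composite_ids(self) -> list[str]:
        return [f"{r}{ID_SEP}{c}" for r, c in
                zip(self.candidates["row_id"], self.candidates["candidate_index"])]


def expand(incomplete: TabularDataset, grid: CandidateGrid) -> GeneratedDataset:
    """Assign every grid value to every incomplete row.

    ``grid.feature_name`` must be the single unknown feature of
    ``incomplete``.  Output ordering is row-major by row id (source order),
    then ascending candidate value.
    """
    if grid.M == 0:  # unreachable: CandidateGrid enforces M >= 1
        raise ValueError("empty candidate grid")
    unknown = incomplete.unknown_features
    if unknown != [grid.feature_name]:
        raise SchemaError(
            f"grid is for {grid.feature_name!r} but incomplete dataset's unknown "
            f"feature(s) are {unknown}")
    row_ids = np.asarray(incomplete.row_ids, dtype=object)
    values = np.asarray(grid.values, dtype=float)
    candidates = pd.DataFrame({
        "row_id": np.repeat(row_ids, grid.M),
        "candidate_index": np.tile(np.arange(grid.M), len(row_ids)),
        "x_hat": np.tile(values, len(row_ids)),
    })
    return GeneratedDataset(incomplete, grid.feature_name, candidates, grid)


def materialize(generated: GeneratedDataset,
                chunk_size: int | None = None) -> TabularDataset:
    """Assemble the full-width candidate table ready for projection.

    Each candidate row carries the d-1 known features of its source row plus
    the synthetic value in the expanded feature's slot; row ids are composite
    ``"<row_id>#<candidate_index>"``.  ``chunk_size`` only controls assembly
    granularity — the result is independent of it.
    """
    frames = [_materialize_chunk(generated, chunk)
              for chunk in _iter_chunks(generated.candidates, chunk_size)]
    full = pd.concat(frames) if len(frames) > 1 else frames[0]
    base = generated.base
    return TabularDataset(list(base.schema), full, base.label_name,
                          allow_partial_missing=True)


def _iter_chunks(df: pd.DataFrame, chunk_size: int | None) -> Iterator[pd.DataFrame]:
    if chunk_size is None or chunk_size >= len(df):
        yield df
        return
    for start in range(0, len(df), chunk_size):
        yield df.iloc[start:start + chunk_size]


def _materialize_chunk(generated: GeneratedDataset, chunk: pd.DataFrame) -> pd.DataFrame:
    base = generated.base
    out = base.frame.loc[chunk["row_id"]].copy()
    out[generated.feature_name] = chunk["x_hat"].to_numpy()
    out.index = pd.Index(
        [f"{r}{ID_SEP}{c}" for r, c in zip(chunk["row_id"], chunk["candidate_index"])])
    return out
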