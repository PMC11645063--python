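import warnings

import numpy as np
import pandas as pd
import pytest

from psdg import (FeatureSpec, FixtureSpec, PipelineConfig, TabularDataset,
                  fit_embedding, make_reference, make_split)

# umap emits benign warnings (n_jobs forced to 1 under a fixed seed, spectral
# init fallbacks on tiny inputs); keep test output readable
warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", message=".*n_jobs value.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


def small_table(values: dict, schema=None, label=None, ids=None):
    """Build a TabularDataset from a dict of columns with minimal ceremony."""
    frame = pd.DataFrame(values)
    if ids is not None:
        frame.index = pd.Index(ids)
    else:
        frame.index = pd.Index([str(i) for i in range(len(frame))])
    if schema is None:
        schema = [FeatureSpec(c, "continuous") for c in values if c != label]
    return TabularDataset(schema, frame, label)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(n_rows=240, n_features=3, class_separation=5.0)


@pytest.fixture(scope="session")
def reference_240(fixture_spec):
    """A complete 240-row labeled fixture shared across embedding tests."""
    return make_reference(fixture_spec, seed=101)


@pytest.fixture(scope="session")
def split_240(fixture_spec):
    """(reference, incomplete, truth) split of a 240-row fixture."""
    return make_split(fixture_spec, seed=101, reference_fraction=0.5)


@pytest.fixture(scope="session")
def fitted_model(split_240):
    """One fitted embedding model reused by every test that only reads it."""
    reference, _, _ = split_240
    return fit_embedding(reference, seed=17)


@pytest.fixture(scope="session")
def case1_result(split_240):
    """One case-1 run at the loosest threshold, shared and never mutated."""
    from psdg import run_case1
    reference, incomplete, _ = split_240
    cfg = PipelineConfig(seed=17, r_min=0.5)
    return run_case1(reference, incomplete, cfg)
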