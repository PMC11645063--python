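"""Composed pipelines: the three cases, iterative synthesis, and imputation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from psdg import (FeatureSpec, FixtureSpec, PipelineConfig, SchemaError,
                  TabularDataset, default_feature_order, make_reference,
                  run_case0, run_case1, run_case2, run_full_synthesis,
                  run_imputation)


class TestCase1:
    def test_counts_and_bounds(self, case1_result, split_240):
        _, incomplete, _ = split_240
        c = case1_result.counts
        assert c["D_g"] == c["N_i"] * c["M"]
        assert c["D_v"] <= c["D_g"]
        assert len(case1_result.rows) == c["D_v"]

    def test_strict_threshold_keeps_candidates_near_neighbor_mean(
            self, split_240):
        reference, incomplete, _ = split_240
        cfg = PipelineConfig(seed=17, r_min=1.0)
        res = run_case1(reference, incomplete, cfg)
        assert len(res.rows) > 0
        eps = 1.0  # integer feature grid default
        assert (res.rows["f_disp"] <= eps).all()

    def test_known_features_bit_equal_to_source(self, case1_result, split_240):
        _, incomplete, _ = split_240
        rows = case1_result.rows
        for rid, grp in rows.groupby("row_id"):
            src = incomplete.frame.loc[rid]
            for col in ("f1", "f2"):
                assert (grp[col] == src[col]).all()

    def test_rerun_is_byte_identical(self, split_240, tmp_path):
        reference, incomplete, _ = split_240
        cfg = PipelineConfig(seed=23, r_min=0.9)
        for name in ("a.csv", "b.csv"):
            run_case1(reference, incomplete, cfg).write_csv(tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_requires_single_missing_feature(self, split_240):
        reference, _, _ = split_240
        cfg = PipelineConfig(seed=1)
        with pytest.raises(SchemaError):
            run_case1(reference, reference, cfg)


class TestCase0:
    @pytest.fixture(scope="class")
    def setup(self, fixture_spec):
        full = make_reference(fixture_spec, seed=55)
        ref = full.select_rows(full.row_ids[:160])
        inc_frame = full.frame.loc[full.row_ids[160:]].copy()
        truth = inc_frame["label"].copy()
        inc_frame["label"] = np.nan
        inc = TabularDataset(list(full.schema), inc_frame, "label")
        cfg = PipelineConfig(seed=3, mode="case0", density_threshold=0.2)
        return ref, inc, truth, run_case0(ref, inc, cfg)

    def test_assignment_counts(self, setup):
        ref, inc, truth, res = setup
        assert res.counts["assigned"] + res.counts["unassigned"] == inc.n_rows
        assert res.counts["assigned"] > 0

    def test_assigned_labels_mostly_match_truth(self, setup):
        # separable classes -> cluster areas recover the held-out labels
        _, _, truth, res = setup
        got = res.rows.set_index("row_id")["y_hat"]
        agree = (got == truth.loc[got.index]).mean()
        assert agree > 0.9

    def test_rows_with_unknown_features_rejected(self, split_240):
        reference, incomplete, _ = split_240
        with pytest.raises(SchemaError):
            run_case0(reference, incomplete, PipelineConfig(seed=1, mode="case0"))


class TestCase2:
    @pytest.fixture(scope="class")
    def pair(self, fixture_spec):
        from psdg import make_split
        ref, inc, truth = make_split(fixture_spec, seed=77,
                                     reference_fraction=0.5, drop_label=True)
        return ref, inc

    def test_output_subset_of_case1(self, pair):
        ref, inc = pair
        cfg2 = PipelineConfig(seed=5, mode="case2", r_min=1.0,
                              density_threshold=0.2)
        cfg1 = dataclasses.replace(cfg2, mode="case1")
        r2 = run_case2(ref, inc, cfg2)
        r1 = run_case1(ref, inc, cfg1)
        keys1 = set(zip(r1.rows["row_id"], r1.rows["candidate_index"]))
        keys2 = set(zip(r2.rows["row_id"], r2.rows["candidate_index"]))
        assert keys2 <= keys1
        assert r2.counts["D_v"] <= r2.counts["D_v_reliability"]

    def test_labels_consistent_with_cluster_stage(self, pair):
        from psdg import assign_labels, fit_clusters, Coordinates2D, fit_embedding
        ref, inc = pair
        cfg = PipelineConfig(seed=5, mode="case2", r_min=1.0,
                             density_threshold=0.2)
        res = run_case2(ref, inc, cfg)
        model = fit_embedding(ref, cfg.embedding, cfg.seed)
        clusters = fit_clusters(model.training_coords,
                                ref.labels.loc[model.training_coords.ids],
                                cfg.density_threshold, cfg.radius_grid)
        coords = Coordinates2D(
            [f"{r}#{c}" for r, c in zip(res.rows["row_id"],
                                        res.rows["candidate_index"])],
            res.rows[["c1", "c2"]].to_numpy(float))
        want = assign_labels(coords, clusters)
        assert list(res.rows["y_hat"]) == want


class TestFullSynthesis:
    @pytest.fixture(scope="class")
    def four_feature_split(self):
        spec = FixtureSpec(n_rows=260, n_features=4, class_separation=5.0)
        full = make_reference(spec, seed=13)
        ref = full.select_rows(full.row_ids[:130])
        inc_frame = full.frame.loc[full.row_ids[130:]].copy()
        inc_frame["age"] = np.nan
        inc_frame["f3"] = np.nan
        inc_frame["label"] = np.nan
        inc = TabularDataset(list(full.schema), inc_frame, "label")
        return ref, inc

    def test_growth_per_iteration(self, four_feature_split):
        ref, inc = four_feature_split
        cfg = PipelineConfig(seed=2, mode="full_synthesis", r_min=1.0,
                             density_threshold=0.2,
                             quantize_levels={"f3": 5},
                             feature_order=("age", "f3"))
        res = run_full_synthesis(ref, inc, cfg)
        its = res.counts["iterations"]
        assert [i["feature"] for i in its] == ["age", "f3"]
        # every iteration's output feeds the next as its incomplete input
        assert its[1]["N_i"] == its[0]["D_v"]
        assert res.counts["final_rows"] == its[-1]["D_v"]
        # generated labels present on the final rows
        assert res.rows["label"].notna().all()

    def test_empty_feature_order_is_identity(self, four_feature_split):
        ref, inc = four_feature_split
        cfg = PipelineConfig(seed=2, mode="full_synthesis", feature_order=())
        res = run_full_synthesis(ref, inc, cfg)
        assert len(res.rows) == inc.n_rows

    def test_unknown_feature_in_order_rejected(self, four_feature_split):
        ref, inc = four_feature_split
        cfg = PipelineConfig(seed=2, mode="full_synthesis",
                             feature_order=("nope",))
        with pytest.raises(SchemaError):
            run_full_synthesis(ref, inc, cfg)

    def test_default_order_by_label_correlation(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 200).astype(float)
        frame = pd.DataFrame({
            "strong": y * 2 + rng.normal(0, 0.1, 200),
            "weak": rng.normal(size=200),
            "medium": y + rng.normal(0, 1.0, 200),
            "y": y,
        }, index=[str(i) for i in range(200)])
        ds = TabularDataset([FeatureSpec(n, "continuous")
                             for n in ("strong", "weak", "medium")], frame, "y")
        order = default_feature_order(ds, ["weak", "medium", "strong"])
        assert order == ["strong", "medium", "weak"]


class TestImputation:
    @pytest.fixture(scope="class")
    def mixed_pattern(self, fixture_spec):
        full = make_reference(fixture_spec, seed=91)
        ref = full.select_rows(full.row_ids[:140])
        rest = full.frame.loc[full.row_ids[140:200]].copy()
        truth = rest["age"].copy()
        rest.iloc[0:30, rest.columns.get_loc("age")] = np.nan  # age-missing rows
        inc = TabularDataset(list(full.schema), rest, "label",
                             allow_partial_missing=True)
        return ref, inc, truth

    def test_single_value_per_cell_and_provenance(self, mixed_pattern):
        ref, inc, truth = mixed_pattern
        cfg = PipelineConfig(seed=6, r_min=0.5, mode="imputation")
        imputed, report = run_imputation(inc, ref, cfg)
        was_missing = inc.frame["age"].isna()
        filled = imputed.frame.loc[was_missing, "age"]
        imputed_report = report[report["status"] == "imputed"]
        # every filled cell is reported with rank 1 and r_c present
        top = imputed_report[imputed_report["rank"] == 1].set_index("row_id")
        for rid, val in filled.dropna().items():
            assert top.loc[rid, "x_hat"] == val
        # untouched cells stay bit-equal
        pd.testing.assert_series_equal(
            imputed.frame.loc[~was_missing, "age"],
            inc.frame.loc[~was_missing, "age"])

    def test_selection_matches_argmax_oracle(self, mixed_pattern, split_240):
        ref, inc, truth = mixed_pattern
        cfg = PipelineConfig(seed=6, r_min=0.5, mode="imputation")
        _, report = run_imputation(inc, ref, cfg)
        # recompute the full validated set and verify the per-row argmax rule
        from psdg import run_case1 as rc1
        missing_ids = inc.frame.index[inc.frame["age"].isna()]
        sub = TabularDataset(list(inc.schema), inc.frame.loc[missing_ids],
                             "label", allow_partial_missing=True)
        v = rc1(ref, sub, dataclasses.replace(cfg, mode="case1")).rows
        top = report[(report["status"] == "imputed") & (report["rank"] == 1)]
        for _, row in top.iterrows():
            grp = v[v["row_id"] == row["row_id"]]
            best = grp.sort_values(["r_c", "f_disp", "x_hat"],
                                   ascending=[False, True, True]).iloc[0]
            assert best["x_hat"] == row["x_hat"]

    def test_top_n_returns_ladder_of_candidates(self, mixed_pattern):
        ref, inc, truth = mixed_pattern
        cfg = PipelineConfig(seed=6, r_min=0.5, mode="imputation")
        _, report = run_imputation(inc, ref, cfg, top_n=3)
        ranks = report[report["status"] == "imputed"].groupby("row_id")["rank"]
        assert ranks.max().max() <= 3
        assert (ranks.min() == 1).all()

    def test_multi_missing_pattern_reported_not_imputed(self, fixture_spec):
        full = make_reference(fixture_spec, seed=92)
        ref = full.select_rows(full.row_ids[:140])
        rest = full.frame.loc[full.row_ids[140:160]].copy()
        rest.iloc[0, [0, 1]] = np.nan  # two features missing in one row
        inc = TabularDataset(list(full.schema), rest, "label",
                             allow_partial_missing=True)
        cfg = PipelineConfig(seed=6, mode="imputation")
        imputed, report = run_imputation(inc, ref, cfg)
        assert (report["status"] == "multi_missing").sum() == 2
        assert imputed.frame.iloc[0].isna().sum() == 2
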