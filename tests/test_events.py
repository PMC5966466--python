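"""Consensus events, HRF regressors, sphere ROIs, ROI GLMs, and the group
and rank tests on event betas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narrsync import events as ev
from narrsync import synthetic as syn
from narrsync.inference import median_split


def _ann_from_labels(label_rows):
    """Annotation table with one sentence per row of rater labels."""
    n = len(label_rows)
    table = pd.DataFrame(
        {
            "sentence_id": [f"s{i + 1:03d}" for i in range(n)],
            "part": 1,
            "onset_tr": np.arange(1, n + 1) * 5 - 4,
            "offset_tr": np.arange(1, n + 1) * 5,
        }
    )
    labels = np.asarray(label_rows, dtype=int)
    for r in range(labels.shape[1]):
        table[f"rater_{r + 1}"] = labels[:, r]
    return table


class TestConsensusEvents:
    def test_three_of_five_included(self):
        ann = _ann_from_labels([[1, 1, 1, 0, 0]])
        evset = ev.consensus_events(ann, min_raters=3)
        assert evset.mentalizing == ("s001",)

    def test_all_zero_labels_go_to_inverse(self):
        ann = _ann_from_labels([[0, 0, 0, 0, 0]])
        evset = ev.consensus_events(ann, min_raters=3)
        assert evset.mentalizing == ()
        assert evset.inverse == ("s001",)

    def test_synthetic_annotations_match_direct_tally(self):
        ann = syn.gen_annotations(100, 5, base_rate=0.25, agreement=0.9, seed=11)
        evset = ev.consensus_events(ann, min_raters=3)
        rater_cols = [f"rater_{r}" for r in range(1, 6)]
        tally = (ann[rater_cols].sum(axis=1) >= 3).sum()
        assert evset.n_events == tally

    def test_min_raters_above_panel_size_rejected(self):
        ann = _ann_from_labels([[1, 0, 1]])
        with pytest.raises(ValueError):
            ev.consensus_events(ann, min_raters=4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=5, max_size=5),
            min_size=1,
            max_size=20,
        )
    )
    def test_mentalizing_and_inverse_partition_all_sentences(self, rows):
        ann = _ann_from_labels(rows)
        evset = ev.consensus_events(ann, min_raters=3)
        both = set(evset.mentalizing) | set(evset.inverse)
        assert both == set(ann["sentence_id"])
        assert not (set(evset.mentalizing) & set(evset.inverse))


class TestHRF:
    def test_vanishes_at_origin(self):
        h = ev.hrf_kernel(1.0)
        assert h[0] == 0.0

    def test_peak_between_four_and_seven_seconds(self):
        h = ev.hrf_kernel(0.1)
        t_peak = 0.1 * np.argmax(h)
        assert 4.0 <= t_peak <= 7.0
        assert h.max() == pytest.approx(1.0)

    def test_positive_integral(self):
        h = ev.hrf_kernel(0.1)
        assert np.trapezoid(h, dx=0.1) > 0

    def test_unknown_model_lists_available(self):
        with pytest.raises(ValueError, match="double_gamma"):
            ev.hrf_kernel(1.0, model="boxcar")


class TestRegressor:
    def test_empty_event_set_gives_zero_regressor(self):
        ann = _ann_from_labels([[0, 0, 0, 0, 0]])
        evset = ev.consensus_events(ann, 3)
        reg = ev.build_regressor(evset, ann, n_tr=50)
        assert np.all(reg == 0)

    def test_identity_kernel_reproduces_impulse(self):
        ann = _ann_from_labels([[1, 1, 1, 1, 1]])
        ann.loc[0, ["onset_tr", "offset_tr"]] = [8, 10]
        evset = ev.consensus_events(ann, 3)
        reg = ev.build_regressor(evset, ann, n_tr=20, hrf=np.array([1.0]))
        expected = np.zeros(20)
        expected[10] = 1.0
        assert np.array_equal(reg, expected)

    def test_block_mode_spans_sentence(self):
        ann = _ann_from_labels([[1, 1, 1, 1, 1]])
        ann.loc[0, ["onset_tr", "offset_tr"]] = [4, 7]
        evset = ev.consensus_events(ann, 3)
        reg = ev.build_regressor(evset, ann, n_tr=15, hrf=np.array([1.0]),
                                 mode="block")
        expected = np.zeros(15)
        expected[4:8] = 1.0
        assert np.array_equal(reg, expected)

    def test_linearity_of_convolution(self):
        ann = _ann_from_labels([[1] * 5, [1] * 5])
        ann.loc[0, ["onset_tr", "offset_tr"]] = [3, 5]
        ann.loc[1, ["onset_tr", "offset_tr"]] = [20, 24]
        both = ev.consensus_events(ann, 3)
        reg_both = ev.build_regressor(both, ann, n_tr=60)
        parts = []
        for sid in ("s001", "s002"):
            single = ev.EventSet(mentalizing=(sid,), inverse=(), min_raters=3)
            parts.append(ev.build_regressor(single, ann, n_tr=60))
        assert np.allclose(reg_both, parts[0] + parts[1], atol=1e-12)

    def test_event_beyond_run_end_names_sentence(self):
        ann = _ann_from_labels([[1] * 5])
        ann.loc[0, ["onset_tr", "offset_tr"]] = [90, 120]
        evset = ev.consensus_events(ann, 3)
        with pytest.raises(ValueError, match="s001"):
            ev.build_regressor(evset, ann, n_tr=100)

    def test_offset_second_rounding_is_ceil(self):
        assert ev.offset_seconds_to_tr(10.2, 1.0) == 11
        assert ev.offset_seconds_to_tr(10.0, 1.0) == 10


class TestSphereROI:
    AFFINE_2MM = np.diag([2.0, 2.0, 2.0, 1.0])

    def test_radius_four_on_two_mm_grid_has_33_voxels(self):
        roi = ev.make_sphere_roi("tpj", (20.0, 20.0, 20.0), 4.0,
                                 self.AFFINE_2MM, (21, 21, 21))
        assert roi.n_voxels == 33

    def test_sub_half_voxel_radius_keeps_center_only(self):
        roi = ev.make_sphere_roi("pt", (20.0, 20.0, 20.0), 0.5,
                                 self.AFFINE_2MM, (21, 21, 21))
        assert roi.n_voxels == 1

    def test_translation_by_one_voxel_shifts_indices(self):
        a = ev.make_sphere_roi("a", (20.0, 20.0, 20.0), 4.0,
                               self.AFFINE_2MM, (30, 30, 30))
        b = ev.make_sphere_roi("b", (22.0, 20.0, 20.0), 4.0,
                               self.AFFINE_2MM, (30, 30, 30))
        assert b.n_voxels == a.n_voxels
        shifted = a.voxels + np.array([1, 0, 0])
        assert np.array_equal(
            b.voxels[np.lexsort(b.voxels.T)], shifted[np.lexsort(shifted.T)]
        )

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            ev.make_sphere_roi("x", (500.0, 0.0, 0.0), 4.0,
                               self.AFFINE_2MM, (10, 10, 10))

    def test_json_sphere_specs_realized_on_grid(self, tmp_path):
        import json

        spec_path = tmp_path / "rois.json"
        spec_path.write_text(json.dumps([
            {"name": "a", "center_mm": [20.0, 20.0, 20.0], "radius_mm": 4.0},
            {"name": "b", "center_mm": [10.0, 10.0, 10.0], "radius_mm": 0.5},
        ]))
        rois = ev.sphere_rois_from_json(spec_path, self.AFFINE_2MM, (21, 21, 21))
        assert [r.name for r in rois] == ["a", "b"]
        assert rois[0].n_voxels == 33
        assert rois[1].n_voxels == 1


class TestExtractROI:
    def test_single_voxel_roi_is_verbatim_series(self, rng):
        vol = rng.standard_normal((4, 4, 4, 30))
        roi = ev.ROIDefinition("one", np.array([[1, 2, 3]]))
        assert np.array_equal(ev.extract_roi_timeseries(vol, roi),
                              vol[1, 2, 3, :])

    def test_two_voxel_roi_is_their_mean(self, rng):
        vol = rng.standard_normal((4, 4, 4, 30))
        roi = ev.ROIDefinition("two", np.array([[0, 0, 0], [1, 1, 1]]))
        expected = (vol[0, 0, 0] + vol[1, 1, 1]) / 2
        assert np.allclose(ev.extract_roi_timeseries(vol, roi), expected)

    def test_random_roi_matches_independent_mean(self, rng):
        vol = rng.standard_normal((5, 5, 5, 20))
        vox = rng.integers(0, 5, size=(10, 3))
        roi = ev.ROIDefinition("ten", vox)
        manual = np.mean([vol[i, j, k] for i, j, k in vox], axis=0)
        assert np.allclose(ev.extract_roi_timeseries(vol, roi), manual,
                           atol=1e-12)

    def test_out_of_grid_voxels_rejected(self, rng):
        vol = rng.standard_normal((3, 3, 3, 10))
        roi = ev.ROIDefinition("bad", np.array([[5, 0, 0]]))
        with pytest.raises(ValueError):
            ev.extract_roi_timeseries(vol, roi)


class TestRoiGLM:
    def test_recovers_exact_affine_relation(self, rng):
        reg = rng.standard_normal(100)
        res = ev.fit_roi_glm(2.0 * reg + 5.0, reg)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(5.0, abs=1e-10)

    def test_orthogonal_series_gives_zero_beta(self, rng):
        reg = rng.standard_normal(200)
        noise = rng.standard_normal(200)
        regc = reg - reg.mean()
        series = noise - (noise @ regc) / (regc @ regc) * regc
        res = ev.fit_roi_glm(series, reg)
        assert res.beta == pytest.approx(0.0, abs=1e-10)

    def test_planted_beta_within_three_standard_errors(self, rng):
        reg = rng.standard_normal(500)
        series = 1.5 * reg + rng.standard_normal(500)
        res = ev.fit_roi_glm(series, reg)
        assert abs(res.beta - 1.5) < 3 * res.se

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ev.fit_roi_glm(np.arange(10.0), np.ones(10))


def _beta_frame(low_betas, high_betas, roi="roi_a", mode="offset"):
    n_low, n_high = len(low_betas), len(high_betas)
    betas = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n_low + n_high)],
            "roi": roi,
            "mode": mode,
            "beta": list(low_betas) + list(high_betas),
        }
    )
    groups = pd.DataFrame(
        {
            "subject_id": betas["subject_id"],
            "group": ["low"] * n_low + ["high"] * n_high,
        }
    )
    return betas, groups


class TestGroupBetaTests:
    def test_identical_group_means_give_t_zero(self):
        betas, groups = _beta_frame([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        table = ev.group_beta_tests(betas, groups)
        row = table.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_negates_t_keeps_p(self):
        betas, groups = _beta_frame([0.1, 0.5, 0.2], [0.9, 1.4, 1.1])
        table = ev.group_beta_tests(betas, groups)
        swapped = groups.copy()
        swapped["group"] = swapped["group"].map({"low": "high", "high": "low"})
        table2 = ev.group_beta_tests(betas, swapped)
        assert table2["t"].iloc[0] == pytest.approx(-table["t"].iloc[0])
        assert table2["p"].iloc[0] == pytest.approx(table["p"].iloc[0])

    def test_equal_variance_df_is_n_minus_two(self):
        betas, groups = _beta_frame(np.arange(11.0), np.arange(11.0) + 1)
        table = ev.group_beta_tests(betas, groups)
        assert table["df"].iloc[0] == 20

    def test_pooled_one_sample_rows_added_for_control_rois(self):
        betas, groups = _beta_frame([1.0, 1.2, 0.8], [1.1, 0.9, 1.3])
        table = ev.group_beta_tests(betas, groups, pooled_rois=("roi_a",))
        pooled = table[table["test"] == "one_sample_pooled"]
        assert len(pooled) == 1
        assert pooled["df"].iloc[0] == 5

    def test_planted_difference_detected_with_high_power(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(100):
            low = rng.normal(0.0, 0.5, 11)
            high = rng.normal(1.0, 0.5, 11)
            betas, groups = _beta_frame(low, high)
            table = ev.group_beta_tests(betas, groups, fdr_q=0.05)
            hits += bool(table["reject"].iloc[0])
        assert hits / 100 > 0.9


class TestBetaRankCorrelation:
    def test_monotone_betas_give_rho_one(self, cohort22):
        rank = cohort22["trait_score"].rank(method="average").to_numpy()
        betas = pd.DataFrame(
            {
                "subject_id": cohort22["subject_id"],
                "roi": "roi_a",
                "mode": "offset",
                "beta": rank * 0.1,
            }
        )
        table = ev.beta_rank_correlation(betas, cohort22)
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        traits = pd.DataFrame(
            {"subject_id": list("abcde"), "trait_score": [10, 20, 30, 40, 50]}
        )
        betas = pd.DataFrame(
            {
                "subject_id": list("abcde"),
                "roi": "r",
                "mode": "offset",
                "beta": [1.0, 3.0, 2.0, 5.0, 4.0],
            }
        )
        table = ev.beta_rank_correlation(betas, traits)
        # ranks of betas: 1,3,2,5,4 vs 1,2,3,4,5 -> rho = 1 - 6*4/(5*24) = 0.8
        assert table["rho"].iloc[0] == pytest.approx(0.8, abs=1e-12)

    def test_null_betas_rarely_exceed_permutation_band(self, cohort22):
        rng = np.random.default_rng(23)
        n_reps, hits = 200, 0
        rank = cohort22["trait_score"].rank(method="average").to_numpy()
        for _ in range(n_reps):
            betas = pd.DataFrame(
                {
                    "subject_id": cohort22["subject_id"],
                    "roi": "r",
                    "mode": "offset",
                    "beta": rng.standard_normal(22),
                }
            )
            table = ev.beta_rank_correlation(betas, cohort22)
            hits += bool(table["p"].iloc[0] < 0.05)
        assert hits / n_reps <= 0.10


class TestOffsetVsBlockRobustness:
    def test_strong_offset_locked_effect_detected_under_both_modes(self):
        # a planted offset-locked response should drive the same group
        # decision whether modeled as impulses or sentence mini-blocks
        traits = syn.gen_trait_scores(22, seed=31)
        groups = median_split(traits)
        ann = syn.gen_annotations(60, seed=32)
        evset = ev.consensus_events(ann, 3)
        offset_reg = ev.build_regressor(evset, ann, n_tr=600, mode="offset")
        decisions = {}
        for mode in ("offset", "block"):
            reg = ev.build_regressor(evset, ann, n_tr=600, mode=mode)
            rows = []
            _, series = syn.gen_roi_responses(
                traits, offset_reg, "trait_scaled", amplitude=3.0,
                between_sd=0.2, noise_sd=1.0, seed=33,
            )
            for i, sid in enumerate(traits["subject_id"]):
                rows.append(
                    {
                        "subject_id": sid,
                        "roi": "r",
                        "mode": mode,
                        "beta": ev.fit_roi_glm(series[i], reg).beta,
                    }
                )
            table = ev.group_beta_tests(pd.DataFrame(rows), groups)
            decisions[mode] = bool(table["reject"].iloc[0])
        assert decisions["offset"] and decisions["block"]
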