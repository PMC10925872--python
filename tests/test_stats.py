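"""Statistics layer: exclusion masks, ROI summaries, rank tests against
independent oracles, 5%-binning, repeated-measures correlation, voxelwise
correlation, cohort summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvrasl.core import LabelMap, Tissue
from cvrasl.cvr_lag import StealMasks, segment_steal
from cvrasl.stats import (benjamini_hochberg, bin_rois, cohort_summary,
                          exclude_nonanalyzed, kruskal_wallis, load_table1,
                          rmcorr, spearman, tissue_roi_summary,
                          voxelwise_correlation, wilcoxon_signed_rank)


class TestExcludeNonanalyzed:
    def test_csf_voxels_are_absent(self, labels):
        mask = exclude_nonanalyzed(labels)
        assert not np.any(mask & labels.mask(Tissue.CSF))
        assert not np.any(mask & labels.mask(Tissue.TREATED_LESION))

    def test_without_exclusions_mask_is_retained_brain(self, rng):
        data = np.where(rng.uniform(size=(6, 6, 3)) > 0.4,
                        int(Tissue.GM), int(Tissue.WM)).astype(np.int16)
        lm = LabelMap(data)
        retained = rng.uniform(size=data.shape) > 0.1
        mask = exclude_nonanalyzed(lm, retained)
        assert np.array_equal(mask, retained)

    def test_matches_set_difference_oracle(self, rng):
        data = rng.integers(0, 8, (8, 8, 4)).astype(np.int16)
        lm = LabelMap(data)
        retained = rng.uniform(size=data.shape) > 0.2
        mask = exclude_nonanalyzed(lm, retained)
        oracle = ((data != 0) & (data != int(Tissue.CSF))
                  & (data != int(Tissue.TREATED_LESION)) & retained)
        assert np.array_equal(mask, oracle)


class TestTissueRoiSummary:
    def test_uniform_map_gives_exact_cell_means(self, labels):
        maps = {"CBF": np.full(labels.data.shape, 5.0)}
        steal = segment_steal(np.where(labels.steal, -1.0, 1.0),
                              exclude_nonanalyzed(labels))
        df = tissue_roi_summary(maps, labels, steal)
        assert np.allclose(df["mean"], 5.0)
        assert np.allclose(df["sd"], 0.0)

    def test_excluded_lesion_values_cannot_leak(self, labels):
        base = np.full(labels.data.shape, 2.0)
        poisoned = base.copy()
        poisoned[labels.mask(Tissue.CSF, Tissue.TREATED_LESION)] = 1e9
        analyzed = exclude_nonanalyzed(labels)
        steal = segment_steal(np.ones(labels.data.shape), analyzed)
        a = tissue_roi_summary({"m": base}, labels, steal,
                               analyzed_mask=analyzed)
        b = tissue_roi_summary({"m": poisoned}, labels, steal,
                               analyzed_mask=analyzed)
        pd.testing.assert_frame_equal(a, b)

    def test_means_match_masked_average_oracle(self, labels, rng):
        arr = rng.normal(10, 3, labels.data.shape)
        analyzed = exclude_nonanalyzed(labels)
        steal = segment_steal(np.where(labels.steal, -1.0, 1.0), analyzed)
        df = tissue_roi_summary({"m": arr}, labels, steal,
                                analyzed_mask=analyzed)
        for _, row in df.iterrows():
            cell = (labels.mask(Tissue[row.tissue]) & analyzed
                    & (steal.steal if row.steal_status == "steal"
                       else steal.non_steal))
            assert row["mean"] == pytest.approx(arr[cell].mean(), abs=1e-12)


def _kw_oracle(groups):
    """Rank-sum Kruskal-Wallis with tie correction, from first principles."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_v = pooled[order]
    i = 0
    pos = 1.0
    while i < len(sorted_v):
        j = i
        while j < len(sorted_v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (pos + pos + (j - i) - 1) / 2.0
        pos += j - i
        i = j
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(sorted_v, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n_total ** 3 - n_total)
    return h / tie


class TestKruskalWallis:
    def test_identical_observations_give_h_zero_p_one(self):
        res = kruskal_wallis([np.ones(5), np.ones(4)])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_textbook_two_group_value(self):
        res = kruskal_wallis([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)

    def test_matches_rank_formula_oracle(self, rng):
        groups = [rng.integers(0, 12, rng.integers(4, 10)).astype(float)
                  for _ in range(4)]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_kw_oracle(groups), abs=1e-10)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.ones(3)])


class TestBenjaminiHochberg:
    def test_single_small_p_rejected(self):
        reject, adj = benjamini_hochberg([0.01], q=0.05)
        assert reject[0]

    def test_step_up_chain_rejects_all_four(self):
        reject, _ = benjamini_hochberg([0.01, 0.02, 0.04, 0.05], q=0.05)
        assert reject.all()

    def test_large_ps_not_rejected(self):
        reject, adj = benjamini_hochberg([0.9, 0.95], q=0.05)
        assert not reject.any()
        assert np.all(adj >= np.array([0.9, 0.95]))

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=20)
        reject, _ = benjamini_hochberg(p, q=0.1)
        order = np.argsort(p)
        ps = p[order]
        thresh = (np.arange(1, 21) / 20.0) * 0.1
        passing = np.where(ps <= thresh)[0]
        k = passing.max() + 1 if passing.size else 0
        oracle = np.zeros(20, dtype=bool)
        oracle[order[:k]] = True
        assert np.array_equal(reject, oracle)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
           st.floats(0.01, 0.2), st.floats(0.01, 0.2))
    def test_rejections_monotone_in_q(self, pvals, q1, q2):
        lo, hi = sorted((q1, q2))
        r_lo, _ = benjamini_hochberg(pvals, q=lo)
        r_hi, _ = benjamini_hochberg(pvals, q=hi)
        assert np.all(r_hi | ~r_lo)  # every lo-rejection survives at hi


class TestSpearman:
    def test_monotone_pairs_give_unit_rho(self):
        x = np.array([1.0, 2, 5, 9])
        assert spearman(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 6, 30).astype(float)  # ties present
        y = rng.integers(0, 6, 30).astype(float)
        res = spearman(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-12)


class TestWilcoxon:
    def test_all_zero_differences_flagged(self):
        res = wilcoxon_signed_rank(np.zeros(5))
        assert res.flagged and np.isnan(res.statistic)

    def test_three_positive_values_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]),
                                   alternative="greater")
        assert res.statistic == 6.0
        assert res.p == pytest.approx(0.125)

    def test_matches_sign_enumeration_oracle(self, rng):
        vals = rng.normal(0.3, 1.0, 9)
        vals = vals[vals != 0]
        res = wilcoxon_signed_rank(vals, alternative="greater")
        ranks = pd.Series(np.abs(vals)).rank().to_numpy()
        w_obs = ranks[vals > 0].sum()
        count = sum(1 for signs in itertools.product([0, 1], repeat=len(vals))
                    if np.sum(ranks * np.array(signs)) >= w_obs - 1e-12)
        p_oracle = count / 2 ** len(vals)
        assert res.statistic == pytest.approx(w_obs)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)


class TestBinRois:
    def test_hundred_distinct_values_make_clean_bins(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10, 1)
        mask = np.ones_like(vals, dtype=bool)
        df = bin_rois(vals, {"other": vals * 2}, mask, n_bins=20,
                      sort_name="aat")
        assert len(df) == 20
        assert df.iloc[0]["mean_aat"] == pytest.approx(3.0)
        assert df.iloc[19]["mean_aat"] == pytest.approx(98.0)
        assert df["n_voxels"].sum() == 100

    def test_constant_map_flagged_degenerate(self):
        vals = np.full((5, 5, 1), 3.0)
        with pytest.raises(ValueError):
            bin_rois(vals, {}, np.ones_like(vals, bool))

    def test_bin_assignment_matches_full_sort_oracle(self, rng):
        vals = rng.normal(size=(8, 8, 4))
        mask = rng.uniform(size=vals.shape) > 0.2
        df = bin_rois(vals, {}, mask, n_bins=20, sort_name="v")
        n = int(mask.sum())
        sorted_vals = np.sort(vals[mask])
        sizes = np.full(20, n // 20)
        sizes[: n % 20] += 1
        edges = np.concatenate([[0], np.cumsum(sizes)])
        for b in range(20):
            oracle_mean = sorted_vals[edges[b]:edges[b + 1]].mean()
            assert df.iloc[b]["mean_v"] == pytest.approx(oracle_mean, abs=1e-12)

    def test_bins_partition_mask_with_balanced_sizes(self, rng):
        vals = rng.normal(size=(9, 9, 3))
        mask = np.ones_like(vals, dtype=bool)
        df = bin_rois(vals, {}, mask, n_bins=20, sort_name="v")
        assert df["n_voxels"].sum() == mask.sum()
        assert df["n_voxels"].max() - df["n_voxels"].min() <= 1

    def test_fewer_voxels_than_bins_rejected(self, rng):
        vals = rng.normal(size=(2, 2, 2))
        with pytest.raises(ValueError):
            bin_rois(vals, {}, np.ones_like(vals, bool), n_bins=20)


def _rmcorr_oracle(df):
    """Two-model ANCOVA: SS with subject dummies only vs dummies + x."""
    subjects = sorted(df["subject"].unique())
    dummies = np.column_stack([(df["subject"] == s).to_numpy(float)
                               for s in subjects])
    y = df["y"].to_numpy(float)
    x = df["x"].to_numpy(float)

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return np.sum((y - design @ beta) ** 2), beta

    ss0, _ = rss(dummies)
    ss1, beta1 = rss(np.column_stack([dummies, x]))
    slope = beta1[-1]
    r = np.sign(slope) * np.sqrt((ss0 - ss1) / ss0)
    dof = len(df) - len(subjects) - 1
    from scipy.stats import f as fdist
    p = float(fdist.sf((ss0 - ss1) / (ss1 / dof), 1, dof))
    return r, slope, dof, p


class TestRmcorr:
    def _table(self, rng, n_sub=5, n_obs=8, slope=1.0, noise=1.0):
        rows = []
        for s in range(n_sub):
            x = rng.normal(s * 2.0, 1.0, n_obs)
            y = slope * x + s * 5.0 + rng.normal(0, noise, n_obs)
            rows += [{"subject": f"s{s}", "x": xv, "y": yv}
                     for xv, yv in zip(x, y)]
        return pd.DataFrame(rows)

    def test_perfect_within_subject_line_gives_unit_r(self, rng):
        df = self._table(rng, slope=1.0, noise=0.0)
        res = rmcorr(df)
        assert res.r_rm == pytest.approx(1.0)
        assert res.p == 0.0

    def test_negative_slope_gives_minus_one(self, rng):
        df = self._table(rng, slope=-2.0, noise=0.0)
        assert rmcorr(df).r_rm == pytest.approx(-1.0)

    def test_matches_two_model_ancova_oracle(self, rng):
        df = self._table(rng, n_sub=6, n_obs=7, slope=0.4, noise=2.0)
        res = rmcorr(df)
        r_o, slope_o, df_o, p_o = _rmcorr_oracle(df)
        assert res.r_rm == pytest.approx(r_o, abs=1e-10)
        assert res.common_slope == pytest.approx(slope_o, abs=1e-10)
        assert res.df == df_o
        assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        df = self._table(rng, n_sub=5, n_obs=9, slope=0.7, noise=1.5)
        res = rmcorr(df)
        out = pg.rm_corr(data=df, x="x", y="y", subject="subject")
        assert res.r_rm == pytest.approx(float(out["r"].iloc[0]), abs=1e-8)
        assert res.df == int(out["dof"].iloc[0])
        assert res.p == pytest.approx(float(out["pval"].iloc[0]), rel=1e-6)

    def test_invariant_under_per_subject_shifts(self, rng):
        df = self._table(rng, n_sub=4, n_obs=10, slope=0.9, noise=1.0)
        res_a = rmcorr(df)
        shifted = df.copy()
        for i, s in enumerate(shifted["subject"].unique()):
            sel = shifted["subject"] == s
            shifted.loc[sel, "x"] += 13.0 * i
            shifted.loc[sel, "y"] -= 7.0 * i
        res_b = rmcorr(shifted)
        assert res_b.r_rm == pytest.approx(res_a.r_rm, abs=1e-12)

    def test_subjects_with_single_row_dropped_with_warning(self, rng):
        df = self._table(rng, n_sub=3, n_obs=5)
        df = pd.concat([df, pd.DataFrame([{"subject": "solo", "x": 1.0,
                                           "y": 2.0}])], ignore_index=True)
        with pytest.warns(UserWarning):
            res = rmcorr(df)
        assert res.n_subjects == 3


class TestVoxelwise:
    def test_identity_and_negation(self, rng):
        a = rng.normal(size=(5, 5, 2))
        masks = {"all": np.ones_like(a, dtype=bool)}
        assert voxelwise_correlation(a, a, masks)["all"] == pytest.approx(1.0)
        assert voxelwise_correlation(a, -a, masks)["all"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        a = rng.normal(size=(6, 6, 3))
        b = rng.normal(size=(6, 6, 3))
        mask = rng.uniform(size=a.shape) > 0.4
        r = voxelwise_correlation(a, b, {"m": mask})["m"]
        av, bv = a[mask], b[mask]
        oracle = (np.mean(av * bv) - av.mean() * bv.mean()) / (av.std() * bv.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_tiny_mask_rejected(self, rng):
        a = rng.normal(size=(2, 2, 1))
        mask = np.zeros_like(a, dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            voxelwise_correlation(a, a, {"m": mask})


class TestCohortSummary:
    def test_packaged_table_reproduces_printed_means(self):
        s = cohort_summary()
        assert s["n_subjects"] == 14
        assert s["means"]["age_years"]["mean"] == pytest.approx(65.1, abs=0.05)
        assert s["means"]["n_bms"]["mean"] == pytest.approx(5.4, abs=0.05)
        assert s["means"]["bms_volume_cc"]["mean"] == pytest.approx(10.7, abs=0.05)
        assert s["means"]["bms_volume_cc"]["n"] == 12
        assert s["means"]["steal_volume_cc"]["mean"] == pytest.approx(62.30, abs=0.02)

    def test_missing_entries_excluded_from_denominator(self):
        df = load_table1()
        s = cohort_summary(df)
        assert s["means"]["edema_volume_cc"]["n"] == 13

    def test_all_missing_column_flagged(self):
        df = pd.DataFrame({"patient": ["a", "b"], "vol": ["-", "-"]})
        s = cohort_summary(df)
        assert s["means"]["vol"]["flagged_empty"]
        assert s["means"]["vol"]["mean"] is None
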