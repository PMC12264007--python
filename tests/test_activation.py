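import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_stepup_enumerate, jaccard, pearson_bruteforce
from spinefusi.activation import (
    bh_fdr,
    compare_in_out_mask,
    group_stats,
    normalize_range,
    peak_and_group_stats,
    pearson_map,
    region_timecourse,
    top_fraction_masks,
)
from spinefusi.activation.stats import ActivationMap
from spinefusi.preprocess import percent_change
from spinefusi.preprocess.percent import PercentChangeStack
from spinefusi.synthetic_data import percent_bp


def _pct_from_array(data: np.ndarray, baseline: int = 0) -> PercentChangeStack:
    d, w, t = data.shape
    return PercentChangeStack(
        data=data,
        baseline_mean_map=np.ones((d, w)),
        analysis_mask=np.ones((d, w), dtype=bool),
        baseline_frames=baseline,
    )


class TestPearsonMap:
    def test_pixel_equal_to_bp_gives_r_one(self):
        bp = np.sin(np.linspace(0, 3, 20))
        data = np.zeros((2, 2, 20))
        data[0, 0] = bp
        data[1, 1] = -bp + 5.0
        data[0, 1] = np.cos(np.linspace(0, 3, 20))
        data[1, 0] = np.linspace(0, 1, 20)
        amap = pearson_map(_pct_from_array(data), bp, window=slice(0, 20))
        assert amap.r[0, 0] == pytest.approx(1.0)
        assert amap.r[1, 1] == pytest.approx(-1.0)
        assert amap.p[0, 0] == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(3, 1, 10))
        bp = rng.normal(size=10)
        amap = pearson_map(_pct_from_array(data), bp, window=slice(0, 10))
        for i in range(3):
            assert amap.r[i, 0] == pytest.approx(
                pearson_bruteforce(data[i, 0], bp), abs=1e-12
            )

    def test_fisher_z_is_atanh(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 2, 15))
        bp = rng.normal(size=15)
        amap = pearson_map(_pct_from_array(data), bp, window=slice(0, 15))
        np.testing.assert_allclose(amap.z, np.arctanh(amap.r), atol=1e-12)

    def test_zero_variance_pixel_dropped(self):
        data = np.random.default_rng(2).normal(size=(2, 2, 12))
        data[0, 0] = 4.2
        bp = np.arange(12.0)
        amap = pearson_map(_pct_from_array(data), bp, window=slice(0, 12))
        assert not amap.analysis_mask[0, 0]
        assert np.isnan(amap.r[0, 0])

    def test_window_too_short(self):
        data = np.zeros((2, 2, 4))
        with pytest.raises(ValueError, match="3 frames"):
            pearson_map(_pct_from_array(data), np.arange(4.0), window=slice(0, 2))

    def test_p_value_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(5)
        data = rng.normal(size=(1, 1, 30))
        bp = rng.normal(size=30)
        amap = pearson_map(_pct_from_array(data), bp, window=slice(0, 30))
        r_ref, p_ref = pearsonr(data[0, 0], bp)
        assert amap.r[0, 0] == pytest.approx(r_ref, abs=1e-12)
        assert amap.p[0, 0] == pytest.approx(p_ref, abs=1e-12)


class TestBhFdr:
    def test_all_zero_all_rejected(self):
        reject, q = bh_fdr(np.zeros(10), alpha=0.01)
        assert reject.all()
        assert q == pytest.approx(np.zeros(10))

    def test_all_one_none_rejected(self):
        reject, q = bh_fdr(np.ones(10), alpha=0.01)
        assert not reject.any()
        assert q == pytest.approx(np.ones(10))

    def test_example_set_matches_enumeration_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041])
        reject, _ = bh_fdr(p, alpha=0.01)
        expected = bh_stepup_enumerate(p, 0.01)
        # oracle: thresholds k*0.01/4 = {0.0025, 0.005, 0.0075, 0.01}; only p=0.001 passes
        assert expected.tolist() == [True, False, False, False]
        assert reject.tolist() == expected.tolist()

    def test_empty_input(self):
        reject, q = bh_fdr(np.array([]))
        assert reject.size == 0 and q.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @settings(max_examples=30, deadline=None)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_oracle_and_statsmodels(self, p, alpha):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        reject, q = bh_fdr(p, alpha=alpha)
        assert reject.tolist() == bh_stepup_enumerate(p, alpha).tolist()
        sm_reject, sm_q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        assert reject.tolist() == sm_reject.tolist()
        np.testing.assert_allclose(q, sm_q, atol=1e-12)


class TestTopFractionMasks:
    @staticmethod
    def _amap_from_r(r: np.ndarray, n: int = 100) -> ActivationMap:
        from scipy.stats import t as tdist

        mask = np.isfinite(r)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * tdist.sf(np.abs(tstat), df=n - 2)
        return ActivationMap(
            r=r, z=np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)), p=p,
            analysis_mask=mask, n_time=n,
        )

    def test_fraction_one_takes_all_significant_positives(self):
        rng = np.random.default_rng(0)
        r = np.concatenate([rng.uniform(0.6, 0.9, 500), rng.uniform(-0.05, 0.05, 500)])
        amap = self._amap_from_r(r.reshape(20, 50))
        pos, neg, _ = top_fraction_masks(amap, fraction=1.0, alpha=0.01)
        sig_pos = (amap.q < 0.01) & (amap.r > 0)
        assert np.array_equal(pos, sig_pos)

    def test_count_rule_ceil(self):
        # 1000 analyzed, all significant, distinct r -> exactly 50 positives
        rng = np.random.default_rng(1)
        r = rng.uniform(0.5, 0.99, 1000)
        amap = self._amap_from_r(r.reshape(20, 50))
        pos, neg, thr = top_fraction_masks(amap, fraction=0.05, alpha=0.01)
        assert pos.sum() == 50
        assert neg.sum() == 0
        # sort oracle: the 50 largest r
        expected = np.sort(r)[-50:]
        assert thr[0] == pytest.approx(expected.min())
        assert set(np.round(amap.r[pos], 12)) == set(np.round(expected, 12))

    def test_masks_disjoint_and_bounded(self):
        rng = np.random.default_rng(2)
        r = np.clip(rng.normal(0, 0.5, 600), -0.99, 0.99)
        amap = self._amap_from_r(r.reshape(20, 30))
        pos, neg, _ = top_fraction_masks(amap, fraction=0.05)
        assert not np.any(pos & neg)
        k = int(np.ceil(0.05 * 600))
        assert pos.sum() <= k and neg.sum() <= k

    def test_no_significant_pixels_warns_empty(self):
        r = np.full((5, 6), 0.01)
        amap = self._amap_from_r(r, n=10)
        with pytest.warns(UserWarning, match="no FDR-significant"):
            pos, neg, thr = top_fraction_masks(amap)
        assert not pos.any() and not neg.any()
        assert np.isnan(thr[0]) and np.isnan(thr[1])

    def test_planted_region_recovery_jaccard(self, tiny_phantom, tiny_trace):
        stack, truth = tiny_phantom
        pct = percent_change(stack)
        bp = percent_bp(tiny_trace)
        amap = pearson_map(pct, bp)
        pos, neg, _ = top_fraction_masks(amap, fraction=0.05, alpha=0.01)
        assert jaccard(pos, truth.pos_mask) >= 0.8
        assert jaccard(neg, truth.neg_mask) >= 0.8

    def test_recovery_degrades_gracefully_with_snr(self, tiny_protocol, tiny_trace):
        from spinefusi.synthetic_data import PhantomConfig, generate_phantom

        scores = []
        for snr in (0.5, 1.0, 2.0, 4.0):
            stack, truth = generate_phantom(
                PhantomConfig(shape=(24, 32), noise_snr=snr),
                tiny_trace, tiny_protocol, seed=3,
            )
            amap = pearson_map(percent_change(stack), percent_bp(tiny_trace))
            pos, _, _ = top_fraction_masks(amap)
            scores.append(jaccard(pos, truth.pos_mask))
        assert all(b >= a - 0.05 for a, b in zip(scores, scores[1:]))  # monotone-ish
        assert scores[-1] >= 0.8


class TestRegionTimecourse:
    def test_single_pixel_mask(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 3, 8))
        pct = _pct_from_array(data)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        tc = region_timecourse(pct, mask)
        assert tc.mean_pct == pytest.approx(data[1, 2])
        assert tc.se_pct == pytest.approx(np.zeros(8))

    def test_uniform_stack_constant_mean(self):
        pct = _pct_from_array(np.full((3, 3, 6), 2.5))
        tc = region_timecourse(pct, np.ones((3, 3), dtype=bool))
        assert tc.mean_pct == pytest.approx(np.full(6, 2.5))

    def test_empty_mask_rejected(self):
        pct = _pct_from_array(np.ones((2, 2, 4)))
        with pytest.raises(ValueError, match="empty"):
            region_timecourse(pct, np.zeros((2, 2), dtype=bool))

    def test_phantom_timecourse_tracks_bp(self, tiny_phantom, tiny_trace):
        stack, truth = tiny_phantom
        pct = percent_change(stack)
        tc = region_timecourse(pct, truth.pos_mask)
        bp = percent_bp(tiny_trace)
        w = slice(stack.baseline_frames, stack.n_frames)
        assert pearson_bruteforce(tc.mean_pct[w], bp[w]) >= 0.95


class TestNormalizeRange:
    def test_unit_interval(self):
        assert normalize_range(np.array([0.0, 5.0, 10.0]), (0, 1)) == pytest.approx([0, 0.5, 1])

    def test_symmetric_interval(self):
        assert normalize_range(np.array([-2.0, 0.0, 2.0]), (-1, 1)) == pytest.approx([-1, 0, 1])

    def test_idempotent_on_unit_series(self):
        x = np.array([0.0, 0.25, 1.0])
        assert normalize_range(x, (0, 1)) == pytest.approx(x)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_range(np.full(5, 3.0))

    @settings(max_examples=30, deadline=None)
    @given(
        xs=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2, max_size=30,
        ).filter(lambda v: max(v) > min(v))
    )
    def test_extremes_attained(self, xs):
        out = normalize_range(np.array(xs), (-1.0, 1.0))
        assert out.min() == pytest.approx(-1.0)
        assert out.max() == pytest.approx(1.0)


class TestGroupStats:
    def test_single_subject(self):
        assert group_stats(np.array([42.0])) == (42.0, 0.0)

    def test_two_values_hand_arithmetic(self):
        # {200, 206}: mean 203, SD 3*sqrt(2), SE = SD/sqrt(2) = 3
        mean, se = group_stats(np.array([200.0, 206.0]))
        assert mean == pytest.approx(203.0)
        assert se == pytest.approx(3.0)

    def test_four_subjects_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        vals = {f"stat{k}": rng.normal(size=4) for k in range(3)}
        out = peak_and_group_stats(vals)
        for name, v in vals.items():
            assert out[name]["mean"] == pytest.approx(v.mean())
            assert out[name]["se"] == pytest.approx(v.std(ddof=1) / 2.0)
            assert out[name]["values"] == pytest.approx(v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_stats(np.array([]))


class TestCompareInOutMask:
    def _activation_with_masks(self, pct, pos, neg):
        shape = pct.shape_px
        amap = ActivationMap(
            r=np.zeros(shape), z=np.zeros(shape), p=np.ones(shape),
            analysis_mask=np.ones(shape, dtype=bool), n_time=pct.n_frames,
        )
        amap.pos_mask = pos
        amap.neg_mask = neg
        return amap

    def test_full_bounds_omits_outside(self):
        pct = _pct_from_array(np.random.default_rng(0).normal(size=(4, 4, 6)))
        pos = np.zeros((4, 4), dtype=bool)
        pos[1, 1] = True
        amap = self._activation_with_masks(pct, pos, np.zeros((4, 4), dtype=bool))
        with pytest.warns(UserWarning, match="outside"):
            tc_in, tc_out = compare_in_out_mask(pct, amap, np.ones((4, 4), dtype=bool))
        assert tc_in is not None and tc_out is None

    def test_empty_activation_omits_both(self):
        pct = _pct_from_array(np.ones((3, 3, 5)))
        amap = self._activation_with_masks(
            pct, np.zeros((3, 3), dtype=bool), np.zeros((3, 3), dtype=bool)
        )
        with pytest.warns(UserWarning):
            tc_in, tc_out = compare_in_out_mask(pct, amap, np.ones((3, 3), dtype=bool))
        assert tc_in is None and tc_out is None

    def test_planted_regions_inside_and_outside(self, tiny_phantom, tiny_trace):
        stack, truth = tiny_phantom
        pct = percent_change(stack)
        bp = percent_bp(tiny_trace)
        amap = pearson_map(pct, bp)
        top_fraction_masks(amap)
        # bounds split the grid so pos region is inside, neg outside
        bounds = np.zeros(pct.shape_px, dtype=bool)
        bounds[:, : pct.shape_px[1] // 2] = True
        tc_in, tc_out = compare_in_out_mask(pct, amap, bounds)
        w = slice(stack.baseline_frames, stack.n_frames)
        assert tc_in is not None and tc_out is not None
        assert abs(pearson_bruteforce(tc_in.mean_pct[w], bp[w])) >= 0.9
        assert abs(pearson_bruteforce(tc_out.mean_pct[w], bp[w])) >= 0.9
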