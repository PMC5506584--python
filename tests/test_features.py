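"""Feature extractors: closed-form examples, independent oracles, and the
symmetry/invariance properties each measure must satisfy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import restcombine as rc
from restcombine.features import _CLIP
from restcombine.synthetic_cohort import build_atlas


class TestFisherZ:
    def test_closed_form(self):
        assert rc.fisher_z(0.0) == 0.0
        assert rc.fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-1.0, 1.0))
    def test_odd_function(self, r):
        assert rc.fisher_z(-r) == pytest.approx(-rc.fisher_z(r), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rc.fisher_z(1.01)

    def test_clipped_at_unity(self):
        assert rc.fisher_z(1.0) == pytest.approx(np.arctanh(_CLIP))


def _atlas_one_roi(shape=(4, 4, 4)):
    atlas = np.zeros(shape, dtype=int)
    atlas[:3, :3, :3] = 1
    return atlas


class TestAlff:
    def test_self_normalisation(self):
        atlas = _atlas_one_roi()
        t = 120
        series = np.tile(np.sin(2 * np.pi * 0.05 * np.arange(t) * 2.0),
                         atlas.shape + (1,))
        vmap = rc.alff(series, atlas, tr_seconds=2.0)
        assert np.allclose(vmap.values[atlas > 0], 1.0)
        assert np.isnan(vmap.values[atlas == 0]).all()

    def test_amplitude_linearity(self):
        atlas = np.zeros((2, 1, 1), dtype=int)
        atlas[:, 0, 0] = [1, 2]
        t = 200
        base = np.sin(2 * np.pi * 0.05 * np.arange(t) * 2.0)
        series = np.stack([2 * base, base])[:, None, None, :]
        vmap = rc.alff(series, atlas, tr_seconds=2.0)
        ratio = vmap.values[0, 0, 0] / vmap.values[1, 0, 0]
        assert ratio == pytest.approx(2.0, abs=1e-9)

    def test_out_of_band_energy_ignored(self):
        rng = np.random.default_rng(2)
        atlas = np.zeros((2, 1, 1), dtype=int)
        atlas[:, 0, 0] = [1, 2]
        t = 400
        times = np.arange(t) * 2.0
        noise = 0.01 * rng.standard_normal(t)
        loud_outside = 100.0 * np.sin(2 * np.pi * 0.2 * times) + noise
        inband = np.sin(2 * np.pi * 0.05 * times) + noise
        series = np.stack([loud_outside, inband])[:, None, None, :]
        vmap = rc.alff(series, atlas, tr_seconds=2.0)
        # the 0.2 Hz tone contributes nothing: voxel 0 sits at the noise floor
        assert vmap.values[0, 0, 0] < 0.2 * vmap.values[1, 0, 0]

    def test_band_without_bins_rejected(self):
        with pytest.raises(ValueError):
            rc.alff(np.zeros((1, 1, 1, 8)), np.ones((1, 1, 1), dtype=int),
                    band=(0.01, 0.02), tr_seconds=0.1)


def kendall_w_bruteforce(series):
    """Direct evaluation of the concordance definition (independent of the
    vectorised implementation): explicit per-series average ranks, explicit
    sum over time of squared rank-sum deviations."""
    m, t = series.shape
    ranks = np.empty((m, t))
    for i in range(m):
        order = np.argsort(series[i], kind="stable")
        rank = np.empty(t)
        rank[order] = np.arange(1, t + 1)
        # average ties
        for val in np.unique(series[i]):
            sel = series[i] == val
            rank[sel] = rank[sel].mean()
        ranks[i] = rank
    s = 0.0
    for tt in range(t):
        r_t = sum(ranks[i, tt] for i in range(m))
        s += (r_t - m * (t + 1) / 2.0) ** 2
    return 12.0 * s / (m * m * (t ** 3 - t))


class TestKendallW:
    def test_perfect_concordance(self):
        base = np.arange(10.0)
        series = np.vstack([base, 2 * base + 1, base ** 3])
        assert rc.kendall_w(series) == pytest.approx(1.0)

    def test_matches_bruteforce_on_hand_ranks(self):
        series = np.array([
            [3.0, 1.0, 4.0, 2.0],
            [2.0, 1.0, 4.0, 3.0],
            [4.0, 2.0, 3.0, 1.0],
        ])
        assert rc.kendall_w(series) == pytest.approx(
            kendall_w_bruteforce(series), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        series = rng.normal(size=(5, 30))
        transformed = np.vstack([
            np.exp(series[0]), 3 * series[1] + 2, series[2] ** 3,
            np.arctan(series[3]), series[4],
        ])
        assert rc.kendall_w(transformed) == pytest.approx(
            rc.kendall_w(series), abs=1e-12)

    def test_constant_series_degenerate(self):
        with pytest.warns(UserWarning):
            assert rc.kendall_w(np.ones((3, 10))) == 0.0


class TestReho:
    def test_shared_signal_is_maximal(self):
        rng = np.random.default_rng(5)
        atlas = build_atlas((8, 8, 8), 8)
        t = 60
        series = rng.normal(size=atlas.shape + (t,))
        latent = rng.normal(size=t)
        series[atlas == 1] = latent  # noiseless shared signal in ROI 1
        vmap = rc.reho(series, atlas)
        vals = vmap.values[atlas > 0]
        assert vmap.values[atlas == 1].min() == vals.max()
        assert np.isclose(vals.mean(), 1.0, atol=1e-9)

    def test_null_w_is_small(self):
        """Independent white noise: raw W concentrates near its null mean,
        far below perfect concordance."""
        rng = np.random.default_rng(6)
        t = 80
        blocks = rng.normal(size=(40, 27, t))
        ws = [rc.kendall_w(b) for b in blocks]
        assert np.mean(ws) < 0.15
        assert max(ws) < 0.3


class TestVmhc:
    def test_identical_and_negated_counterparts(self):
        atlas = build_atlas((8, 8, 8), 8)
        rng = np.random.default_rng(3)
        series = rng.normal(size=atlas.shape + (50,))
        sym = series + series[::-1]          # mirror-symmetric component
        anti = series - series[::-1]         # mirror-antisymmetric
        zmax = rc.fisher_z(1.0)
        v_sym = rc.vmhc(sym, atlas)
        v_anti = rc.vmhc(anti, atlas)
        assert np.allclose(v_sym.values[atlas > 0], zmax)
        assert np.allclose(v_anti.values[atlas > 0], -zmax)

    def test_map_is_mirror_symmetric(self):
        atlas = build_atlas((8, 8, 8), 8)
        rng = np.random.default_rng(12)
        series = rng.normal(size=atlas.shape + (40,))
        vmap = rc.vmhc(series, atlas)
        vals = np.where(np.isnan(vmap.values), 0.0, vmap.values)
        assert np.allclose(vals, vals[::-1], atol=1e-10)


class TestFcs:
    def test_constructed_exact_correlations(self):
        """Three voxels built so r12 = r13 = 0.5 exactly give
        FCS_1 = fisher_z(0.5)."""
        t = 64
        times = np.arange(t)
        u = np.sqrt(2.0 / t) * np.cos(2 * np.pi * 3 * times / t)
        w2 = np.sqrt(2.0 / t) * np.cos(2 * np.pi * 7 * times / t)
        w3 = np.sqrt(2.0 / t) * np.cos(2 * np.pi * 11 * times / t)
        v2 = 0.5 * u + np.sqrt(0.75) * w2
        v3 = 0.5 * u + np.sqrt(0.75) * w3
        series = np.stack([u, v2, v3])[:, None, None, :]
        gm = np.ones((3, 1, 1), dtype=int)
        vmap = rc.fcs(series, gm)
        assert vmap.values[0, 0, 0] == pytest.approx(rc.fisher_z(0.5),
                                                     abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=(5, 1, 1, 40))
        gm = np.ones((5, 1, 1), dtype=int)
        base = rc.fcs(series, gm).values[:, 0, 0]
        perm = np.array([3, 0, 4, 1, 2])
        permuted = rc.fcs(series[perm], gm).values[:, 0, 0]
        assert np.allclose(permuted, base[perm], atol=1e-12)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            rc.fcs(np.zeros((1, 1, 1, 10)), np.ones((1, 1, 1), dtype=int))


class TestSeedNetwork:
    def test_reference_scale_invariance_and_null(self):
        atlas = build_atlas((8, 8, 8), 8)
        rng = np.random.default_rng(4)
        series = rng.normal(size=atlas.shape + (60,))
        m1 = rc.seed_network(series, atlas, (1, 5))
        m2 = rc.seed_network(series * 3.0, atlas, (1, 5))
        assert np.allclose(m1.values[atlas > 0], m2.values[atlas > 0],
                           atol=1e-9)
        # voxels outside the seed are independent noise: z near 0 on average
        outside = m1.values[(atlas > 1) & (atlas != 5)]
        assert abs(np.mean(outside)) < 0.1

    def test_empty_seed_rejected(self):
        atlas = build_atlas((8, 8, 8), 8)
        with pytest.raises(ValueError):
            rc.seed_network(np.zeros(atlas.shape + (10,)), atlas, (42,))


class TestRoiMeans:
    def test_constant_map_and_single_voxel_rois(self):
        atlas = np.zeros((2, 2, 1), dtype=int)
        atlas[0, 0, 0] = 1
        atlas[1, 1, 0] = 2
        vmap = rc.VoxelMap(values=np.full((2, 2, 1), 7.5), measure_tag="x")
        fv = rc.roi_means(vmap, atlas, 2)
        assert np.allclose(fv.values, 7.5)
        vmap.values[1, 1, 0] = -3.0
        assert rc.roi_means(vmap, atlas, 2).values[1] == -3.0

    def test_empty_roi_rejected(self):
        atlas = np.ones((2, 2, 1), dtype=int)
        vmap = rc.VoxelMap(values=np.zeros((2, 2, 1)), measure_tag="x")
        with pytest.raises(ValueError):
            rc.roi_means(vmap, atlas, 2)


class TestTemporalCorrelation:
    def test_full_atlas_length(self):
        rng = np.random.default_rng(0)
        fv = rc.temporal_correlation(rng.normal(size=(116, 40)))
        assert len(fv.values) == 116 * 115 // 2 == 6670
        assert fv.names[0] == "2~1"

    def test_shared_latent_pair_dominates(self):
        rng = np.random.default_rng(5)
        t = 300
        latent = rng.normal(size=t)
        ts = np.vstack([
            latent + 0.3 * rng.normal(size=t),
            latent + 0.3 * rng.normal(size=t),
            rng.normal(size=t),
        ])
        fv = rc.temporal_correlation(ts)
        vals = dict(zip(fv.names, fv.values))
        assert vals["2~1"] > 1.0
        assert abs(vals["3~1"]) < 0.3 and abs(vals["3~2"]) < 0.3


class TestGranger:
    def test_var2_order_recovery(self):
        """Order selection on strong VAR(2) data: never under-selects, picks
        exactly 2 in the clear majority of seeds (AIC's over-selection
        probability is bounded away from zero, so the rate is not ~100%)."""
        rng = np.random.default_rng(0)
        picks = []
        for _ in range(100):
            t = 500
            x = np.zeros(t)
            y = np.zeros(t)
            e = rng.standard_normal((2, t))
            for k in range(2, t):
                x[k] = 0.5 * x[k - 1] - 0.45 * x[k - 2] + e[0, k]
                y[k] = 0.4 * y[k - 1] - 0.45 * y[k - 2] + 0.35 * x[k - 2] + e[1, k]
            picks.append(rc.var_order_aic(x, y, p_max=6))
        picks = np.array(picks)
        assert np.bincount(picks).argmax() == 2
        assert (picks >= 2).mean() >= 0.95
        assert (picks == 2).mean() >= 0.65

    def test_white_noise_prefers_smallest_order(self):
        rng = np.random.default_rng(1)
        picks = [
            rc.var_order_aic(rng.standard_normal(400),
                             rng.standard_normal(400), p_max=5)
            for _ in range(60)
        ]
        assert np.bincount(picks).argmax() == 1

    def test_coupled_pair_exceeds_null_quantile(self):
        rng = np.random.default_rng(2)
        p = 1
        t = 300
        hits = 0
        n = 100
        for _ in range(n):
            x = rng.standard_normal(t)
            y = np.zeros(t)
            y[1:] = 0.8 * x[:-1]
            y += rng.standard_normal(t)
            f = rc.granger_f(x, y, p)
            crit = stats.f.ppf(0.99, p, (t - p) - 2 * p - 1)
            hits += f > crit
        assert hits >= int(0.95 * n)

    def test_independent_pair_follows_f_distribution(self):
        rng = np.random.default_rng(3)
        p = 2
        t = 200
        fs = [
            rc.granger_f(rng.standard_normal(t), rng.standard_normal(t), p)
            for _ in range(300)
        ]
        ks = stats.kstest(fs, stats.f(p, (t - p) - 2 * p - 1).cdf)
        assert ks.pvalue > 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(150)
        y = rng.standard_normal(150) + 0.5 * np.roll(x, 1)
        f1 = rc.granger_f(x, y, 2)
        f2 = rc.granger_f(3.0 * x - 7.0, 0.5 * y + 2.0, 2)
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestGcMatrix:
    def test_length_and_names(self):
        rng = np.random.default_rng(0)
        fv = rc.gc_matrix(rng.standard_normal((4, 120)), p_max=3)
        assert len(fv.values) == 4 * 3
        assert fv.names[0] == "1->2"
        assert fv.names[-1] == "4->3"

    def test_time_reversal_swaps_direction(self):
        rng = np.random.default_rng(6)
        wins = 0
        n = 20
        for _ in range(n):
            t = 300
            x = rng.standard_normal(t)
            y = np.zeros(t)
            y[1:] = 0.8 * x[:-1]
            y += 0.5 * rng.standard_normal(t)
            ts = np.vstack([x, y])
            fwd = rc.gc_matrix(ts, p_max=3)
            rev = rc.gc_matrix(ts[:, ::-1], p_max=3)
            f = dict(zip(fwd.names, fwd.values))
            r = dict(zip(rev.names, rev.values))
            wins += (f["1->2"] > f["2->1"]) and (r["2->1"] > r["1->2"])
        assert wins >= int(0.9 * n)


class TestExtractFeatures:
    def test_name_alignment_across_subjects(self, small_cohort):
        subjects, _ = small_cohort
        seed_map = rc.default_seed_map(8)
        sets = [
            rc.extract_features(rc.preprocess_subject(s), seed_map=seed_map,
                                p_max=3)
            for s in subjects[:2]
        ]
        assert set(sets[0].features) == set(rc.FEATURE_TYPE_ORDER)
        for ft in sets[0].features:
            assert sets[0].features[ft].names == sets[1].features[ft].names
        assert len(sets[0].features["TC"].values) == 8 * 7 // 2
        assert len(sets[0].features["GC"].values) == 8 * 7
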