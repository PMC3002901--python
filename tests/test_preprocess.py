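"""Normalization stage: background erasure, MA algebra, loess, filtering."""

import numpy as np
import pandas as pd
import pytest

from crhnet import preprocess
from crhnet.containers import TwoColorArraySet
from crhnet.preprocess import (
    complete_case_filter,
    compute_ma,
    filter_background,
    loess_normalize,
    loess_smooth,
)
from crhnet.synthetic import SyntheticConfig, generate_intensity_dataset


def make_arrayset(cy3, cy5, dye=None, tips=None):
    cy3 = np.atleast_2d(np.asarray(cy3, dtype=float))
    cy5 = np.atleast_2d(np.asarray(cy5, dtype=float))
    n_spots, n_arrays = cy3.shape
    spots = pd.DataFrame(
        {"print_tip": tips if tips is not None else np.ones(n_spots, int)},
        index=[f"sp{i}" for i in range(n_spots)],
    )
    arrays = pd.DataFrame(
        {
            "time_h": np.arange(n_arrays, dtype=float),
            "dye": dye if dye is not None else ["treated_cy3"] * n_arrays,
        },
        index=[f"a{j}" for j in range(n_arrays)],
    )
    mk = pd.DataFrame(True, index=spots.index, columns=arrays.index)
    return TwoColorArraySet(
        spots, arrays,
        pd.DataFrame(cy3, index=spots.index, columns=arrays.index),
        pd.DataFrame(cy5, index=spots.index, columns=arrays.index),
        mk,
    )


class TestFilterBackground:
    def test_lowest_value_erased(self):
        arr = make_arrayset(
            np.arange(1, 11)[:, None], np.full((10, 1), 100.0)
        )
        out = filter_background(arr, 0.10)
        assert not out.mask.iloc[0, 0]          # intensity 1 erased
        assert out.mask.iloc[1:, 0].all()

    def test_fraction_zero_is_identity(self):
        arr = make_arrayset(np.arange(1, 11)[:, None], np.arange(1, 11)[:, None])
        out = filter_background(arr, 0.0)
        assert out.mask.to_numpy().all()

    def test_tie_break_erases_floor_count(self):
        # 20 identical values in one channel: floor(0.1 * 20) = 2 erased,
        # stable tie-break by spot order
        arr = make_arrayset(np.full((20, 1), 5.0), np.linspace(10, 20, 20)[:, None])
        with pytest.warns(UserWarning, match="identical"):
            out = filter_background(arr, 0.10)
        erased = np.flatnonzero(~out.mask.to_numpy()[:, 0])
        # cy3 erases spots 0,1 by tie-break; cy5's lowest two are also 0,1
        assert list(erased) == [0, 1]

    def test_bad_fraction_rejected(self):
        arr = make_arrayset([[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            filter_background(arr, 1.0)


class TestComputeMa:
    def test_equal_channels(self):
        ma = compute_ma(make_arrayset([[1024.0]], [[1024.0]]))
        assert ma.m.iloc[0, 0] == 0.0
        assert ma.a.iloc[0, 0] == 10.0

    def test_orientation_antisymmetry(self):
        a1 = make_arrayset([[4096.0]], [[1024.0]], dye=["treated_cy3"])
        a2 = make_arrayset([[4096.0]], [[1024.0]], dye=["treated_cy5"])
        assert compute_ma(a1).m.iloc[0, 0] == 2.0
        assert compute_ma(a2).m.iloc[0, 0] == -2.0

    def test_ma_is_algebraic_inverse(self):
        rng = np.random.default_rng(0)
        cy3 = rng.uniform(10, 1e4, size=(50, 2))
        cy5 = rng.uniform(10, 1e4, size=(50, 2))
        ma = compute_ma(make_arrayset(cy3, cy5))
        m, a = ma.m.to_numpy(), ma.a.to_numpy()
        np.testing.assert_allclose(2 ** (a + m / 2), cy3, rtol=1e-10)
        np.testing.assert_allclose(2 ** (a - m / 2), cy5, rtol=1e-10)

    def test_zero_intensity_masked(self):
        ma = compute_ma(make_arrayset([[0.0], [10.0]], [[5.0], [10.0]]))
        assert not ma.mask.iloc[0, 0]
        assert ma.mask.iloc[1, 0]


class TestLoess:
    def test_constant_m_normalizes_to_zero(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 200)
        fit = loess_smooth(a, np.full(200, 0.7))
        np.testing.assert_allclose(fit, 0.7, atol=1e-8)

    def test_linear_trend_matches_reference_smoother(self):
        """On exactly linear M(A), interior fitted values agree with an
        independent local-regression implementation to 1e-6."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        a = np.linspace(0, 10, 200)
        m = 0.5 * a
        ours = loess_smooth(a, m, span=0.75)
        ref = lowess(m, a, frac=0.75, return_sorted=False)
        interior = slice(20, 180)
        assert np.max(np.abs(ours[interior] - m[interior])) < 1e-6
        assert np.max(np.abs(ours[interior] - ref[interior])) < 1e-6

    def test_injected_print_tip_bias_removed(self):
        cfg = SyntheticConfig(
            n_spots=800, n_print_tips=4, n_de_genes=0, noise_sd=0.15,
            dye_bias_amplitude=0.8, dye_bias_curvature=0.5, seed=8,
        )
        arrays, _ = generate_intensity_dataset(cfg)
        ma = compute_ma(arrays)
        norm = loess_normalize(ma)
        m, a = norm.m.to_numpy(), norm.a.to_numpy()
        tips = norm.spots["print_tip"].to_numpy()
        # binned mean of normalized M within each print tip stays below the
        # replicate noise on every array
        bins = np.linspace(cfg.a_range[0], cfg.a_range[1], 5)
        worst = 0.0
        for j in range(m.shape[1]):
            for tip in np.unique(tips):
                for b in range(4):
                    sel = (
                        (tips == tip)
                        & (a[:, j] >= bins[b]) & (a[:, j] <= bins[b + 1])
                    )
                    if sel.sum() >= 10:
                        worst = max(worst, abs(m[sel, j].mean()))
        assert worst < cfg.noise_sd

    def test_idempotent_to_tolerance(self):
        # noise-free fixture: the first pass removes the bias exactly, so a
        # second pass must leave the residuals essentially unchanged
        cfg = SyntheticConfig(
            n_spots=300, n_print_tips=2, n_de_genes=0, noise_sd=0.0,
            dye_bias_amplitude=0.6, dye_bias_curvature=0.4, seed=9,
        )
        arrays, _ = generate_intensity_dataset(cfg)
        once = loess_normalize(compute_ma(arrays))
        twice = loess_normalize(once)
        assert np.nanmax(np.abs(twice.m.to_numpy() - once.m.to_numpy())) < 1e-6

    def test_small_group_falls_back_to_whole_array(self):
        rng = np.random.default_rng(2)
        cy3 = rng.uniform(100, 1000, size=(30, 1))
        cy5 = rng.uniform(100, 1000, size=(30, 1))
        tips = np.r_[np.ones(27, int), np.full(3, 2, int)]
        arr = make_arrayset(cy3, cy5, tips=tips)
        with pytest.warns(UserWarning, match="whole-array"):
            loess_normalize(compute_ma(arr), min_group_size=10)


class TestOrientationCoherence:
    def test_swapping_dye_labels_negates_m_end_to_end(self):
        cfg = SyntheticConfig(n_spots=120, n_print_tips=2, n_de_genes=5,
                              seed=11)
        arrays, _ = generate_intensity_dataset(cfg)
        flipped = arrays.copy()
        flipped.arrays["dye"] = np.where(
            flipped.arrays["dye"] == "treated_cy3",
            "treated_cy5", "treated_cy3",
        )
        ma, ma_f = compute_ma(arrays), compute_ma(flipped)
        np.testing.assert_allclose(ma_f.m.to_numpy(), -ma.m.to_numpy())
        np.testing.assert_allclose(ma_f.a.to_numpy(), ma.a.to_numpy())
        n, nf = loess_normalize(ma), loess_normalize(ma_f)
        np.testing.assert_allclose(
            nf.m.to_numpy(), -n.m.to_numpy(), atol=1e-10
        )


class TestCompleteCase:
    def test_masked_spot_dropped(self):
        arr = make_arrayset(
            np.full((3, 2), 100.0), np.full((3, 2), 200.0)
        )
        arr.mask.iloc[1, 0] = False
        out = complete_case_filter(compute_ma(arr))
        assert list(out.values.index) == ["sp0", "sp2"]

    def test_no_mask_keeps_all(self):
        arr = make_arrayset(np.full((5, 2), 100.0), np.full((5, 2), 150.0))
        assert complete_case_filter(compute_ma(arr)).n_genes == 5

    def test_survivor_count_matches_presence_scan(self):
        cfg = SyntheticConfig(n_spots=500, n_print_tips=4, n_de_genes=0,
                              seed=12)
        arrays, _ = generate_intensity_dataset(cfg)
        filtered = filter_background(arrays, 0.10)
        ma = compute_ma(filtered)
        expected = int(ma.mask.to_numpy().all(axis=1).sum())
        out = complete_case_filter(ma)
        assert out.n_genes == expected
        # filtering never invents values
        norm_m = ma.m.to_numpy()
        assert set(np.round(out.matrix().ravel(), 12)) <= set(
            np.round(norm_m[np.isfinite(norm_m)], 12)
        )

    def test_empty_result_raises(self):
        arr = make_arrayset([[100.0], [100.0]], [[100.0], [100.0]])
        arr.mask.iloc[:, 0] = False
        with pytest.raises(ValueError, match="no spot"):
            complete_case_filter(compute_ma(arr))
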