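"""Image descriptors, paired class-level shift tests, and heatmap border
mass."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from fieldshift.shiftstats import (
    DESCRIPTOR_NAMES,
    bonferroni_adjust,
    border_mass_ratio,
    class_domain_aggregate,
    compute_descriptors,
    descriptor_table,
    paired_shift_test,
    signed_rank_p,
)


class TestDescriptors:
    def test_names_complete(self):
        d = compute_descriptors(np.full((32, 32, 3), 0.5))
        assert set(d) == set(DESCRIPTOR_NAMES)
        assert len(DESCRIPTOR_NAMES) == 17

    def test_constant_midgray(self):
        d = compute_descriptors(np.full((32, 32, 3), 0.5))
        for name in (
            "mean_saturation", "sobel_edge_density", "border_edge_density",
            "center_edge_density", "laplacian_variance", "gray_entropy",
            "foreground_occupancy", "lbp_entropy", "mean_hue_dispersion",
            "edge_orientation_entropy",
        ):
            assert d[name] == pytest.approx(0.0, abs=1e-12), name

    def test_saturated_red(self):
        img = np.zeros((32, 32, 3))
        img[..., 0] = 1.0
        d = compute_descriptors(img)
        assert d["mean_saturation"] == pytest.approx(1.0)
        assert d["sobel_edge_density"] == 0.0

    def test_vertical_step_edge_counting(self):
        img = np.zeros((32, 32, 3))
        img[:, 16:, :] = 1.0
        d = compute_descriptors(img)
        # Sobel magnitude exceeds threshold on the two boundary columns only
        assert d["sobel_edge_density"] == pytest.approx(2 / 32)
        assert d["center_edge_density"] > d["border_edge_density"]

    def test_bounded_quantities(self, rng):
        for _ in range(5):
            img = rng.random((24, 24, 3))
            d = compute_descriptors(img)
            for name in ("sobel_edge_density", "border_edge_density",
                         "center_edge_density", "foreground_occupancy"):
                assert 0.0 <= d[name] <= 1.0
            for name in ("gray_entropy", "lbp_entropy",
                         "edge_orientation_entropy"):
                assert d[name] >= 0.0

    def test_flip_invariance(self, rng):
        img = rng.random((24, 28, 3))
        base = compute_descriptors(img)
        for flipped in (img[::-1], img[:, ::-1]):
            d = compute_descriptors(np.ascontiguousarray(flipped))
            for name in DESCRIPTOR_NAMES:
                assert d[name] == pytest.approx(base[name], abs=1e-9), name

    def test_rejects_grayscale(self):
        with pytest.raises(ValueError):
            compute_descriptors(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            compute_descriptors(np.zeros((8, 32, 3)))


class TestAggregate:
    def test_single_image_cells(self, rng):
        imgs = rng.random((4, 20, 20, 3))
        df = descriptor_table(imgs)
        agg = class_domain_aggregate(
            df, [0, 0, 1, 1], ["source", "target", "source", "target"]
        )
        got = agg.loc[(0, "source")]
        assert np.allclose(got.to_numpy(), df.iloc[0].to_numpy())

    def test_duplicates_leave_mean_unchanged(self, rng):
        imgs = rng.random((2, 20, 20, 3))
        df1 = descriptor_table(imgs)
        df2 = pd.concat([df1, df1], ignore_index=True)
        a1 = class_domain_aggregate(df1, [0, 0], ["source", "target"])
        a2 = class_domain_aggregate(df2, [0, 0, 0, 0],
                                    ["source", "target", "source", "target"])
        assert np.allclose(a1.to_numpy(), a2.to_numpy())

    def test_groupby_oracle(self, rng):
        df = pd.DataFrame(rng.random((12, 3)), columns=list("abc"))
        labels = rng.integers(0, 2, 12)
        domains = np.where(rng.random(12) < 0.5, "source", "target")
        if not all(
            {"source", "target"} <= set(domains[labels == k]) for k in (0, 1)
        ):
            labels, domains = np.array([0, 0, 1, 1] * 3), np.array(
                ["source", "target"] * 6
            )
        agg = class_domain_aggregate(df, labels, domains)
        for (k, dom) in agg.index:
            sel = (labels == k) & (domains == dom)
            assert np.allclose(agg.loc[(k, dom)].to_numpy(),
                               df[sel].mean().to_numpy())

    def test_missing_class_excluded_with_warning(self, rng):
        df = pd.DataFrame(rng.random((3, 2)), columns=["a", "b"])
        with pytest.warns(RuntimeWarning):
            agg = class_domain_aggregate(df, [0, 0, 1],
                                         ["source", "target", "source"])
        assert 1 not in agg.index.get_level_values(0)


def enumeration_p(diffs):
    """Independent 2^n sign-enumeration oracle (midranks for ties)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    le = np.mean(ws <= w_obs + 1e-12)
    ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(le, ge))


class TestSignedRank:
    def test_three_positive_differences(self):
        r = paired_shift_test(np.zeros(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert r.p_raw == pytest.approx(2 / 2**5)

    def test_minimum_attainable_for_21_classes(self):
        rng = np.random.default_rng(0)
        diffs = rng.uniform(0.5, 1.5, 21)
        r = paired_shift_test(np.zeros(21), diffs)
        assert r.exact
        assert r.p_raw == pytest.approx(2 / 2**21, rel=1e-9)

    def test_cohens_d_definition(self):
        rng = np.random.default_rng(1)
        diffs = rng.standard_normal(21)
        diffs = (diffs - diffs.mean()) / diffs.std(ddof=1) + 1.0  # mean 1, sd 1
        r = paired_shift_test(np.zeros(21), diffs)
        assert r.cohens_d == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_difference_flagged(self):
        with pytest.warns(RuntimeWarning):
            r = paired_shift_test(np.zeros(6), np.full(6, 2.0))
        assert math.isinf(r.cohens_d) and r.cohens_d > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        d = rng.standard_normal(n)
        if seed % 2:  # force midrank ties
            d = np.round(d, 0) + 0.5 * np.sign(d)
            d = d[d != 0]
            if len(d) < 5:
                d = np.r_[d, 1.5, -1.5, 2.5]
        p, _ = signed_rank_p(d)
        assert p == pytest.approx(enumeration_p(d), abs=1e-10)

    def test_all_zero_differences(self):
        p, exact = signed_rank_p(np.zeros(8))
        assert p == 1.0 and exact


class TestBonferroni:
    def test_scaling_and_cap(self):
        adj = bonferroni_adjust([0.001, 0.1], m=17)
        assert adj[0] == pytest.approx(0.017)
        assert adj[1] == 1.0

    def test_monotone_never_below_raw(self, rng):
        p = rng.uniform(1e-6, 1.0, 17)
        adj = bonferroni_adjust(p)
        assert np.all(adj >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5], m=0)


class TestBorderMass:
    def test_uniform_counting(self):
        assert border_mass_ratio(np.ones((10, 10))) == pytest.approx(0.64)

    def test_central_and_corner_mass(self):
        h = np.zeros((11, 11))
        h[5, 5] = 1.0
        assert border_mass_ratio(h) == 0.0
        h2 = np.zeros((10, 10))
        h2[0, 0] = 3.0
        assert border_mass_ratio(h2) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            border_mass_ratio(np.zeros((8, 8)))
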