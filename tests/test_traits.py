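"""Tortuosity, fractal, and trait-vector assembly."""

import math

import numpy as np
import pytest
from conftest import arc, semicircle

from retimorph.synthetic import GrowthConfig, grow_vessel_tree
from retimorph.pipeline import extract_traits, measure_image
from retimorph.tracking import count_junctions, skeletonize
from retimorph.traits import (
    CLASS_NAMES,
    FRACTAL_NAMES,
    TRAIT_NAMES,
    aggregate_tortuosity,
    anchor_points,
    assemble_trait_vector,
    class_traits,
    fractal_traits,
    smooth_branch,
    tortuosity_basis,
    tortuosity_traits,
)
from retimorph.vesselmap import split_by_caliber


def quadrature_oracle(fx, fy, dfx, dfy, ddfx, ddfy, t0, t1, n=20000):
    """Independent oracle: dense numerical quadrature of the arc-length and
    curvature integrals for a parametric curve (x(t), y(t))."""
    t = np.linspace(t0, t1, n)
    xp, yp = dfx(t), dfy(t)
    xpp, ypp = ddfx(t), ddfy(t)
    speed = np.hypot(xp, yp)
    kappa = (xp * ypp - yp * xpp) / speed**3
    ds = speed * (t1 - t0) / (n - 1)
    arc_len = float(np.sum(ds))
    chord = float(np.hypot(fx(t1) - fx(t0), fy(t1) - fy(t0)))
    T2 = float(np.sum(np.abs(kappa) * ds))
    T3 = float(np.sum(kappa**2 * ds))
    return {
        "T1": arc_len / chord,
        "T2": T2,
        "T3": T3,
        "T4": T2 / arc_len,
        "T5": T3 / arc_len,
        "T6": T2 / chord,
        "T7": T3 / chord,
    }


class TestTortuosityBasis:
    def test_straight_line_arc_chord_and_zero_curvature(self):
        pts = np.column_stack([np.zeros(100), np.arange(100.0)])
        b = tortuosity_basis(pts)
        assert b.arc == pytest.approx(99.0)
        assert b.chord == pytest.approx(99.0)
        assert np.allclose(b.kappa, 0.0, atol=1e-12)

    def test_semicircle_arc_over_chord_is_half_pi(self):
        b = tortuosity_basis(semicircle(50.0))
        assert b.arc / b.chord == pytest.approx(math.pi / 2, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tortuosity_basis(np.zeros((3, 2)))

    def test_sine_curvature_matches_quadrature_oracle(self):
        x = np.arange(0.0, 201.0)
        pts = np.column_stack([x, 10.0 * np.sin(x / 20.0)])
        b = tortuosity_basis(pts)
        oracle = quadrature_oracle(
            fx=lambda t: t,
            fy=lambda t: 10 * np.sin(t / 20),
            dfx=lambda t: np.ones_like(t),
            dfy=lambda t: 0.5 * np.cos(t / 20),
            ddfx=lambda t: np.zeros_like(t),
            ddfy=lambda t: -0.025 * np.sin(t / 20),
            t0=0.0,
            t1=200.0,
        )
        assert float(np.sum(np.abs(b.kappa) * b.ds)) == pytest.approx(oracle["T2"], rel=0.03)
        assert float(np.sum(b.kappa**2 * b.ds)) == pytest.approx(oracle["T3"], rel=0.03)


class TestTortuosityTraits:
    def test_straight_line_traits(self):
        pts = np.column_stack([np.arange(120.0), np.zeros(120)])
        t = tortuosity_traits(pts)
        assert t["t1"] == pytest.approx(1.0, abs=1e-9)
        assert t["t2"] == pytest.approx(1.0, abs=1e-6)
        for k in range(3, 15):
            assert abs(t[f"t{k}"]) < 1e-6
        assert t["t15"] == pytest.approx(1.0, abs=0.02)

    def test_semicircle_values(self):
        t = tortuosity_traits(semicircle(50.0))
        assert t["t1"] == pytest.approx(math.pi / 2, rel=0.02)
        assert t["t3"] == pytest.approx(math.pi, rel=0.02)  # total curvature = angle
        assert t["t5"] == pytest.approx(math.pi / 50, rel=0.03)  # L / R^2

    def test_sampled_traits_match_quadrature_on_sine(self):
        x = np.arange(0.0, 201.0)
        pts = np.column_stack([x, 10.0 * np.sin(x / 20.0)])
        oracle = quadrature_oracle(
            fx=lambda t: t,
            fy=lambda t: 10 * np.sin(t / 20),
            dfx=lambda t: np.ones_like(t),
            dfy=lambda t: 0.5 * np.cos(t / 20),
            ddfx=lambda t: np.zeros_like(t),
            ddfy=lambda t: -0.025 * np.sin(t / 20),
            t0=0.0,
            t1=200.0,
        )
        t = tortuosity_traits(pts)
        for k in range(1, 8):
            assert t[f"t{2 * k - 1}"] == pytest.approx(oracle[f"T{k}"], rel=0.03), f"T{k}"

    @pytest.mark.parametrize("m", [2.0, 4.0])
    def test_scaling_laws_on_circular_arc(self, m):
        base = tortuosity_traits(arc(40.0, math.pi / 2))
        mag = tortuosity_traits(arc(40.0 * m, math.pi / 2))
        assert mag["t1"] == pytest.approx(base["t1"], rel=0.02)  # T1 invariant
        assert mag["t3"] == pytest.approx(base["t3"], rel=0.02)  # T2 = angle, invariant
        assert mag["t5"] == pytest.approx(base["t5"] / m, rel=0.03)  # T3 ~ 1/m
        assert mag["t7"] == pytest.approx(base["t7"] / m, rel=0.03)  # T4 ~ 1/m
        assert mag["t9"] == pytest.approx(base["t9"] / m**2, rel=0.03)  # T5 ~ 1/m^2
        assert mag["t11"] == pytest.approx(base["t11"] / m, rel=0.03)  # T6 ~ 1/m
        assert mag["t13"] == pytest.approx(base["t13"] / m**2, rel=0.03)  # T7 ~ 1/m^2

    def test_arc_chord_ratio_at_least_one_for_random_open_polylines(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = np.cumsum(rng.normal(0, 1, size=(30, 2)), axis=0)
            t = tortuosity_traits(pts)
            if math.isfinite(t["t1"]):
                assert t["t1"] >= 1.0 - 1e-9

    def test_closed_branch_chord_traits_missing(self):
        th = np.linspace(0, 2 * math.pi, 100)
        ring = np.column_stack([20 * np.cos(th), 20 * np.sin(th)])
        t = tortuosity_traits(ring)
        for name in ("t1", "t11", "t13"):
            assert math.isnan(t[name])
        assert t["t3"] == pytest.approx(2 * math.pi, rel=0.05)

    def test_smoothing_contracts_noisy_digitized_line(self):
        rng = np.random.default_rng(3)
        x = np.arange(0.0, 80.0)
        y = np.round(rng.normal(0, 0.5, size=80))  # pixel-lattice jitter
        pts = np.column_stack([x, y])
        sampled = tortuosity_basis(pts, "sampled")
        smoothed = tortuosity_basis(smooth_branch(pts), "smoothed")
        assert smoothed.arc <= sampled.arc
        t = tortuosity_traits(pts)
        assert t["t15"] <= 1.0


class TestAggregate:
    def test_single_branch_identity(self):
        row = dict.fromkeys([f"t{i}" for i in range(1, 16)], 2.0)
        assert aggregate_tortuosity([row])["t1"] == 2.0

    def test_mean_and_permutation_invariance(self):
        a = dict.fromkeys([f"t{i}" for i in range(1, 16)], 1.0)
        b = dict.fromkeys([f"t{i}" for i in range(1, 16)], 1.2)
        assert aggregate_tortuosity([a, b])["t1"] == pytest.approx(1.1)
        assert aggregate_tortuosity([b, a]) == aggregate_tortuosity([a, b])

    def test_no_branches_gives_all_missing(self):
        out = aggregate_tortuosity([])
        assert all(math.isnan(v) for v in out.values())


def brute_force_boxes(mask: np.ndarray, b: int) -> int:
    """Naive double-loop scan over the grid-aligned box tiling."""
    h, w = mask.shape
    n = 0
    for i in range(0, h, b):
        for j in range(0, w, b):
            if mask[i : i + b, j : j + b].any():
                n += 1
    return n


class TestFractal:
    def test_plane_filling_gives_two_exactly_at_dyadic_size(self):
        f = fractal_traits(np.ones((512, 512), dtype=bool))
        for name in FRACTAL_NAMES:
            assert f[name] == pytest.approx(2.0, abs=1e-12)

    def test_straight_line_gives_one(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[256, :] = True
        f = fractal_traits(mask)
        for name in FRACTAL_NAMES:
            assert f[name] == pytest.approx(1.0, abs=0.05)

    def test_matches_brute_force_scanner_on_random_mask(self):
        rng = np.random.default_rng(11)
        mask = rng.random((300, 420)) < 0.2
        f = fractal_traits(mask)
        for s in range(2, 9):
            b = 2**s
            r = math.ceil(max(mask.shape) / b)
            n = brute_force_boxes(mask, b)
            if r <= 1:
                assert math.isnan(f[f"f{s}"])
            else:
                assert f[f"f{s}"] == pytest.approx(math.log(n) / math.log(r), abs=1e-12)

    def test_scale_coarser_than_image_is_missing(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:60, 50:60] = True
        f = fractal_traits(mask)
        assert math.isnan(f["f8"])  # 256-px boxes: resolution 1

    def test_empty_mask_all_missing(self):
        f = fractal_traits(np.zeros((64, 64), dtype=bool))
        assert all(math.isnan(v) for v in f.values())


class TestAnchorSampling:
    def test_endpoints_preserved(self):
        pts = np.column_stack([np.arange(23.0), np.zeros(23)])
        a = anchor_points(pts, spacing=5)
        assert np.array_equal(a[0], pts[0])
        assert np.array_equal(a[-1], pts[-1])

    def test_short_chains_untouched(self):
        pts = np.zeros((2, 2))
        assert len(anchor_points(pts)) == 2


class TestAssemble:
    @pytest.fixture(scope="class")
    def split_masks(self):
        vmap, _ = grow_vessel_tree(GrowthConfig(seed=5, bifurcation_budget=12, shape=(256, 256)))
        m = measure_image(vmap)
        um = float(np.mean(m.branch_calibers))
        split = split_by_caliber(vmap, m.branch_points, m.branch_calibers, um=um)
        return vmap, split

    def test_75_values_in_fixed_order(self, split_masks):
        _, split = split_masks
        vectors = assemble_trait_vector(split.masks)
        assert set(vectors) == set(CLASS_NAMES)
        total = 0
        for cls in CLASS_NAMES:
            assert list(vectors[cls].keys()) == list(TRAIT_NAMES)
            total += len(vectors[cls])
        assert total == 75

    def test_empty_class_is_all_missing_others_populated(self, split_masks):
        vmap, split = split_masks
        masks = dict(split.masks)
        masks["Thin"] = np.zeros_like(masks["Total"])
        vectors = assemble_trait_vector(masks)
        assert all(math.isnan(v) for v in vectors["Thin"].values())
        assert math.isfinite(vectors["Total"]["j2"])

    def test_total_junctions_equal_full_map_skeleton_counts(self, split_masks):
        vmap, split = split_masks
        vectors = assemble_trait_vector(split.masks)
        j = count_junctions(skeletonize(vmap.pixels))
        assert vectors["Total"]["j1"] == j.j1
        assert vectors["Total"]["j2"] == j.j2
        assert vectors["Total"]["j3"] == j.j3


class TestExtractTraits:
    def test_three_rows_per_image_and_determinism(self):
        maps = [
            grow_vessel_tree(GrowthConfig(seed=s, bifurcation_budget=8, shape=(256, 256)))[0]
            for s in (1, 2, 3)
        ]
        df1 = extract_traits(maps)
        df2 = extract_traits(maps)
        assert len(df1) == 9
        assert list(df1.columns[-25:]) == list(TRAIT_NAMES)
        assert df1.equals(df2)

    def test_pooled_um_is_shared_across_images(self):
        maps = [
            grow_vessel_tree(GrowthConfig(seed=s, bifurcation_budget=8, shape=(256, 256)))[0]
            for s in (4, 5)
        ]
        df = extract_traits(maps)
        assert df["Um"].nunique() == 1
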