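"""Minimum Feret diameter, area filter, size bins, fiber-type composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from sarcophen.morph import (
    FiberShape,
    bin_by_feret,
    fibers_to_frame,
    filter_by_area,
    generate_fibers,
    min_feret,
    read_fibers,
    type_composition,
    write_fibers,
)

UNIT_SQUARE = [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]


def brute_force_width(vertices, step_deg=0.1):
    """Oracle: minimum projection width over a fine rotation grid."""
    pts = np.asarray(vertices, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    normals = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = pts @ normals.T
    return float((proj.max(axis=0) - proj.min(axis=0)).min())


def square_fiber(side, **kwargs):
    return FiberShape(np.asarray(UNIT_SQUARE) * side, **kwargs)


class TestMinFeret:
    def test_unit_square(self):
        assert min_feret(UNIT_SQUARE) == pytest.approx(1.0)

    def test_right_triangle_altitude(self):
        # legs 3 and 4: min width is the altitude to the hypotenuse, 12/5
        assert min_feret([[0, 0], [4, 0], [0, 3]]) == pytest.approx(2.4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.uniform(0, 10, size=(rng.integers(4, 12), 2))
            hull_feret = min_feret(pts)
            assert hull_feret == pytest.approx(
                brute_force_width(pts), rel=1e-3
            )

    @settings(deadline=None, max_examples=40)
    @given(
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts = np.array([[0, 0], [5, 0], [6, 3], [2, 5], [-1, 2]], dtype=float)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + [dx, dy]
        assert min_feret(moved) == pytest.approx(min_feret(pts), rel=1e-6)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_linear_scaling(self, scale):
        pts = np.array([[0, 0], [5, 0], [6, 3], [2, 5]], dtype=float)
        assert min_feret(pts * scale) == pytest.approx(scale * min_feret(pts), rel=1e-9)

    def test_concave_polygon_equals_its_hull(self):
        concave = [[0, 0], [4, 0], [4, 4], [2, 1.0], [0, 4]]
        hull_only = [[0, 0], [4, 0], [4, 4], [0, 4]]
        assert min_feret(concave) == pytest.approx(min_feret(hull_only))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            min_feret([[0, 0], [1, 1], [2, 2]])


class TestAreaFilter:
    def test_boundary_kept(self):
        fibers = [
            square_fiber(np.sqrt(a), fiber_id=str(a)) for a in (299.0, 300.0, 301.0)
        ]
        kept = filter_by_area(fibers, min_area=300.0)
        assert sorted(f.fiber_id for f in kept) == ["300.0", "301.0"]

    def test_zero_threshold_noop(self):
        fibers = [square_fiber(s) for s in (1.0, 5.0)]
        assert filter_by_area(fibers, min_area=0.0) == fibers

    def test_all_small_warns_and_empties(self):
        with pytest.warns(UserWarning, match="area filter"):
            out = filter_by_area([square_fiber(1.0)], min_area=300.0)
        assert out == []

    def test_idempotent(self):
        fibers = [square_fiber(s) for s in (10.0, 20.0, 30.0)]
        once = filter_by_area(fibers, min_area=300.0)
        assert filter_by_area(once, min_area=300.0) == once


class TestBinning:
    def test_direct_binning(self):
        fibers = [square_fiber(s) for s in (10.0, 20.0, 30.0)]
        dist = bin_by_feret(fibers, [0.0, 15.0, 25.0, 35.0])
        assert dist.counts == (1, 1, 1)
        assert dist.overflow == 0

    def test_empty_input(self):
        dist = bin_by_feret([], [0.0, 10.0, 20.0])
        assert dist.counts == (0, 0) and dist.total == 0

    def test_overflow_reported_and_counts_conserved(self):
        fibers = [square_fiber(s) for s in (5.0, 15.0, 99.0)]
        dist = bin_by_feret(fibers, [10.0, 20.0])
        assert dist.counts == (1,)
        assert dist.overflow == 2
        assert dist.total == len(fibers)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_by_feret([], [10.0, 10.0])

    def test_size_shift_detected_by_chi_square(self):
        """Populations generated at mean 40 vs 30 differ at p < 0.01, n=500."""
        edges = np.arange(0.0, 75.0, 7.5)
        big = bin_by_feret(generate_fibers(500, feret_mean=40.0, seed=1), edges)
        small = bin_by_feret(generate_fibers(500, feret_mean=30.0, seed=2), edges)
        table = np.array([big.counts, small.counts])
        table = table[:, table.sum(axis=0) > 0]
        _, p, _, _ = chi2_contingency(table)
        assert p < 0.01


class TestComposition:
    def test_arithmetic(self):
        labels = ["IIb"] * 50 + ["IIa"] * 30 + ["IIx"] * 20
        comp = type_composition(labels)
        assert comp.percent == {"I": 0.0, "IIa": 30.0, "IIx": 20.0, "IIb": 50.0}
        assert sum(comp.percent.values()) == 100.0

    def test_single_type(self):
        comp = type_composition(["I", "I"])
        assert comp.percent["I"] == 100.0

    def test_unlabeled_excluded_from_denominator(self):
        comp = type_composition(["IIb", "IIb", None, "", "IIa"])
        assert comp.n_typed == 3 and comp.n_unlabeled == 2
        assert comp.percent["IIb"] == pytest.approx(200.0 / 3)

    def test_empty_after_exclusion_rejected(self):
        with pytest.raises(ValueError):
            type_composition([None, ""])

    def test_sums_to_exactly_100(self):
        rng = np.random.default_rng(3)
        labels = list(rng.choice(["I", "IIa", "IIx", "IIb"], size=97))
        assert sum(type_composition(labels).percent.values()) == 100.0

    def test_group_difference_power(self):
        """IIb fraction 0.64 vs 0.46, 4 samples of 300 fibers: t-test p<0.05."""
        from sarcophen.stats import two_group_test

        hits = 0
        n_reps = 20
        rng_seed = 0
        for rep in range(n_reps):
            def iib_percent(prob, seed):
                fibers = generate_fibers(
                    300, type_probs=(0.02, 0.16, 0.18 + (0.64 - prob), prob),
                    seed=seed,
                )
                return type_composition([f.label for f in fibers]).percent["IIb"]

            wt = [iib_percent(0.64, 100 * rep + i) for i in range(4)]
            hom = [iib_percent(0.46, 100 * rep + 50 + i) for i in range(4)]
            if two_group_test(wt, hom).p_value < 0.05:
                hits += 1
        assert hits >= 0.9 * n_reps


class TestGenerator:
    def test_empty(self):
        assert generate_fibers(0, seed=1) == []

    def test_all_iib(self):
        fibers = generate_fibers(30, type_probs=(0, 0, 0, 1), seed=4)
        assert all(f.label == "IIb" for f in fibers)

    def test_self_consistency_within_2_percent(self):
        for f in generate_fibers(50, seed=5):
            assert abs(f.min_feret - f.target_feret) / f.target_feret < 0.02

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            generate_fibers(5, type_probs=(0.5, 0.5, 0.5, 0.5))

    def test_determinism(self):
        a = generate_fibers(5, seed=6)
        b = generate_fibers(5, seed=6)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.vertices, fb.vertices)
            assert fa.label == fb.label


class TestShapesAndIO:
    def test_self_intersecting_rejected(self):
        bowtie = [[0, 0], [2, 2], [2, 0], [0, 2]]
        with pytest.raises(ValueError):
            FiberShape(np.asarray(bowtie, dtype=float))

    def test_round_trip(self, tmp_path):
        fibers = generate_fibers(8, seed=7, sample_id="s1")
        path = tmp_path / "fibers.csv"
        write_fibers(fibers, path)
        back = read_fibers(path)
        assert len(back) == len(fibers)
        for fa, fb in zip(fibers, back):
            np.testing.assert_allclose(fb.vertices, fa.vertices)
            assert fb.label == fa.label
            assert fb.min_feret == pytest.approx(fa.min_feret)

    def test_frame_has_vertex_rows(self):
        fibers = generate_fibers(3, seed=8)
        frame = fibers_to_frame(fibers)
        assert len(frame) == sum(len(f.vertices) for f in fibers)
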