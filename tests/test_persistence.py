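"""Reduction engine, brute-force oracles, Betti curves, bottleneck distance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatph import (
    InputError,
    InvariantViolation,
    PersistenceDiagram,
    SizeError,
    UsageError,
    betti_at,
    bottleneck_distance,
    cubical_persistence,
    diagram_to_betti_curve,
    lower_star_cubical,
    make_fixture,
    reduce_complex,
    vietoris_rips,
)
from fatph.filtration import FilteredComplex

SQRT2 = math.sqrt(2.0)


def path_complex():
    """v1 at 0, v2 at 5, edge at 7 — one merge."""
    return FilteredComplex(
        dims=np.array([0, 0, 1]),
        values=np.array([0.0, 5.0, 7.0]),
        boundaries=[(), (), (0, 1)],
    )


def diagram(intervals, dims=None):
    """Helper: diagram from [(birth, death), ...]."""
    b = np.array([i[0] for i in intervals], dtype=float)
    d = np.array([i[1] for i in intervals], dtype=float)
    k = np.zeros(len(intervals), int) if dims is None else np.asarray(dims)
    return PersistenceDiagram(k, b, d)


class TestReduce:
    def test_single_merge(self):
        dg = reduce_complex(path_complex())
        b, d = dg.intervals(0)
        assert sorted(zip(b, d)) == [(0.0, math.inf), (5.0, 7.0)]

    def test_unit_square_rips(self):
        dg = reduce_complex(vietoris_rips(make_fixture("grid"), eps_max=2))
        b1, d1 = dg.intervals(1)
        assert len(b1) == 1
        assert b1[0] == pytest.approx(1.0, abs=0) and d1[0] == pytest.approx(SQRT2, abs=0)
        b0, d0 = dg.intervals(0)
        assert sorted(d0) == pytest.approx([1.0, 1.0, 1.0, math.inf])

    def test_circle_has_one_persistent_loop(self):
        dg = reduce_complex(vietoris_rips(make_fixture("circle"), eps_max=3))
        b, d = dg.finite(1)
        assert len(b) == 1 and dg.n_essential(1) == 0
        assert b[0] == pytest.approx(2 * math.sin(math.pi / 20))
        assert d[0] - b[0] > 1.0

    def test_zero_persistence_excluded_by_default(self):
        fc = lower_star_cubical(np.full((2, 2), 3.0))
        assert len(reduce_complex(fc)) == 1  # only the essential component
        kept = reduce_complex(fc, keep_zero=True)
        assert len(kept) > 1
        b, d = kept.intervals(0)
        assert np.sum(np.isfinite(d)) == 3  # three zero-length merges

    def test_non_monotone_complex_rejected(self):
        fc = FilteredComplex(
            dims=np.array([0, 0, 1]),
            values=np.array([0.0, 0.0, -1.0]),
            boundaries=[(), (), (0, 1)],
        )
        with pytest.raises(InvariantViolation):
            reduce_complex(fc)

    def test_one_essential_component_per_final_component(self):
        # two clusters far apart, truncated Rips never joins them
        dg = reduce_complex(vietoris_rips(make_fixture("two_clusters"), eps_max=2.0))
        assert dg.n_essential(0) == 2


class TestBettiAt:
    def test_path_complex_before_edge(self):
        assert betti_at(path_complex(), 0, 6.0) == 2
        assert betti_at(path_complex(), 0, 7.0) == 1

    def test_annulus_ring_threshold(self):
        fc = lower_star_cubical(make_fixture("annulus_image"))
        assert betti_at(fc, 0, 0.0) == 1
        assert betti_at(fc, 1, 0.0) == 1

    def test_unit_square_open_loop(self):
        fc = vietoris_rips(make_fixture("grid"), eps_max=2)
        assert betti_at(fc, 0, 1.2) == 1
        assert betti_at(fc, 1, 1.2) == 1
        assert betti_at(fc, 1, 1.5) == 0  # triangles fill the loop at sqrt(2)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(UsageError):
            betti_at(path_complex(), 2, 1.0)


class TestBettiCurve:
    def test_half_open_convention(self):
        dg = diagram([(0.0, math.inf), (5.0, 7.0)])
        curve = diagram_to_betti_curve(dg, 0, [6.0, 7.0])
        assert curve.values.tolist() == [2, 1]

    def test_unsorted_thresholds_rejected(self):
        dg = diagram([(0.0, 1.0)])
        with pytest.raises(InputError):
            diagram_to_betti_curve(dg, 0, [1.0, 0.5])

    @settings(max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_curve_matches_oracle_on_random_clouds(self, seed):
        pts = np.random.default_rng(seed).uniform(0, 2, (7, 2))
        fc = vietoris_rips(pts, eps_max=1.5)
        dg = reduce_complex(fc, validate=False)
        crit = np.unique(fc.values)
        grid = np.unique(np.concatenate([crit, crit + 1e-6, [crit[-1] + 1]]))
        for k in (0, 1):
            curve = diagram_to_betti_curve(dg, k, grid)
            assert [betti_at(fc, k, t) for t in grid] == curve.values.tolist()

    def test_dim0_curve_nonincreasing_after_last_vertex_birth(self, rng):
        pts = rng.uniform(0, 3, (10, 2))
        fc = vietoris_rips(pts, eps_max=5.0)
        dg = reduce_complex(fc, validate=False)
        grid = np.unique(fc.values)  # vertices all born at 0
        vals = diagram_to_betti_curve(dg, 0, grid).values
        assert np.all(np.diff(vals) <= 0)


class TestFastCubical:
    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**16), r=st.integers(2, 7), c=st.integers(2, 7))
    def test_agrees_with_reduction(self, seed, r, c):
        patch = np.random.default_rng(seed).integers(0, 6, (r, c)).astype(float)
        fast = cubical_persistence(patch)
        slow = reduce_complex(lower_star_cubical(patch), validate=False)
        assert fast.same_intervals(slow)

    def test_no_essential_loops_in_planar_images(self, rng):
        patch = rng.uniform(0, 10, (12, 12))
        assert cubical_persistence(patch).n_essential(1) == 0

    def test_annulus_loop_interval(self):
        dg = cubical_persistence(make_fixture("annulus_image"))
        b, d = dg.finite(1)
        assert list(zip(b, d)) == [(0.0, 200.0)]  # shifted: ring 0, background 200


class TestBottleneck:
    def test_identical_diagrams_distance_zero(self):
        dg = diagram([(0.0, 2.0), (1.0, 5.0)])
        assert bottleneck_distance(dg, dg, 0) == 0.0

    def test_single_point_vs_empty_matches_diagonal(self):
        dg = diagram([(1.0, 3.0)])
        empty = diagram([])
        assert bottleneck_distance(dg, empty, 0) == pytest.approx(1.0)

    def test_shifted_death(self):
        a = diagram([(0.0, 2.0)])
        b = diagram([(0.0, 2.5)])
        assert bottleneck_distance(a, b, 0) == pytest.approx(0.5)

    def test_essential_classes_paired_by_birth(self):
        a = diagram([(0.0, math.inf)])
        b = diagram([(0.3, math.inf)])
        assert bottleneck_distance(a, b, 0) == pytest.approx(0.3)
        assert bottleneck_distance(a, diagram([]), 0) == math.inf

    def test_exhaustive_size_cap(self):
        big = diagram([(float(i), float(i + 2)) for i in range(9)])
        with pytest.raises(SizeError):
            bottleneck_distance(big, big, 0, method="exhaustive")
        assert bottleneck_distance(big, big, 0, method="matching") == 0.0

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_matching_solver_agrees_with_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        def rand_dg(n):
            b = rng.uniform(0, 3, n)
            return diagram(list(zip(b, b + rng.uniform(0, 2, n))))
        a, b = rand_dg(rng.integers(0, 6)), rand_dg(rng.integers(0, 6))
        ex = bottleneck_distance(a, b, 0, method="exhaustive")
        hk = bottleneck_distance(a, b, 0, method="matching")
        assert hk == pytest.approx(ex, abs=1e-12)

    def test_cubical_stability_small(self, rng):
        patch = rng.uniform(0, 20, (8, 8))
        for delta in (0.5, 2.0):
            noisy = patch + rng.uniform(-delta, delta, patch.shape)
            a = cubical_persistence(patch, apply_shift=False)
            b = cubical_persistence(noisy, apply_shift=False)
            for k in (0, 1):
                assert bottleneck_distance(a, b, k) <= delta + 1e-9


class TestDiagramIO:
    def test_tsv_roundtrip_with_inf(self, tmp_path):
        dg = diagram([(0.0, math.inf), (1.5, 2.25)], dims=[0, 1])
        path = tmp_path / "dg.tsv"
        dg.to_tsv(path)
        assert "inf" in path.read_text()
        back = PersistenceDiagram.from_tsv(path)
        assert back.same_intervals(dg)

    def test_birth_after_death_rejected(self):
        with pytest.raises(InputError):
            diagram([(3.0, 1.0)])
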