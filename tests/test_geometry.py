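import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trapline as tl

from _oracle import brute_force_open_path


class TestBuildArray:
    def test_two_platforms_unit_distance(self):
        arr = tl.build_array("pair", {"1": (0, 0), "2": (1, 0)})
        assert arr.dist[0, 1] == 1.0
        assert arr.dist[0, 0] == 0.0

    def test_regular_pentagon_chord(self):
        arr = tl.pentagon(circumradius=1.0)
        # adjacent chord of the unit-circumradius pentagon: 2 sin 36deg
        expected = 2 * math.sin(math.radians(36))
        for k in range(5):
            assert arr.dist[k, (k + 1) % 5] == pytest.approx(expected, abs=1e-12)

    def test_double_trapezoid_fixture(self, double_trapezoid):
        arr = double_trapezoid
        assert arr.n == 6
        assert np.allclose(arr.dist, arr.dist.T)
        assert np.all(np.diag(arr.dist) == 0)
        assert tl.count_routes(arr.n) == 720
        # fixture pinned to the original coordinate scale via the prior centre
        assert tl.prior_center(arr) == pytest.approx(4.78, abs=1e-9)

    def test_distance_matrix_invariants(self, z_array):
        d = z_array.dist
        off = d[~np.eye(z_array.n, dtype=bool)]
        assert np.all(off > 0)
        # Euclidean distances satisfy the triangle inequality
        n = z_array.n
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    @pytest.mark.parametrize(
        "coords,err",
        [
            ({"A": (0, 0)}, "at least two"),
            ({"A": (0, 0), "B": (0, 0)}, "coincident"),
            ({"A": (0, 0), "B": (math.nan, 0)}, "finite"),
        ],
    )
    def test_rejects_bad_input(self, coords, err):
        with pytest.raises(ValueError, match=err):
            tl.build_array("bad", coords)

    def test_array_csv_round_trip(self, tmp_path, double_trapezoid):
        import pandas as pd

        path = tmp_path / "dt.csv"
        pd.DataFrame(
            {
                "label": double_trapezoid.labels,
                "x": double_trapezoid.coords[:, 0],
                "y": double_trapezoid.coords[:, 1],
            }
        ).to_csv(path, index=False)
        loaded = tl.load_array_csv(path, name="double_trapezoid")
        assert loaded.labels == double_trapezoid.labels
        assert np.allclose(loaded.dist, double_trapezoid.dist)


class TestRouteDistance:
    def test_single_platform_zero(self, collinear):
        assert tl.route_distance(collinear, ["A"]) == 0.0

    def test_straight_line(self, collinear):
        assert tl.route_distance(collinear, ["A", "B", "C"]) == pytest.approx(2)

    def test_revisits_counted(self, collinear):
        # A->B (1) + B->A (1) + A->C (2)
        assert tl.route_distance(collinear, ["A", "B", "A", "C"]) == pytest.approx(4)

    def test_unknown_label_rejected(self, collinear):
        with pytest.raises(KeyError, match="unknown platform"):
            tl.route_distance(collinear, ["A", "Z"])


class TestCountRoutes:
    @pytest.mark.parametrize("n,expected", [(6, 720), (5, 120), (1, 1)])
    def test_factorial_counts(self, n, expected):
        assert tl.count_routes(n) == expected


class TestOptimalOpenPath:
    def test_collinear_end_to_end(self, collinear):
        opt = tl.optimal_open_path(collinear)
        assert opt.length == pytest.approx(2)
        assert opt.sequence in (("A", "B", "C"), ("C", "B", "A"))

    def test_unit_square_three_sides(self, unit_square):
        assert tl.optimal_open_path(unit_square).length == pytest.approx(3)

    def test_pentagon_perimeter_minus_one_edge(self):
        arr = tl.pentagon(circumradius=1.0)
        side = 2 * math.sin(math.radians(36))
        opt = tl.optimal_open_path(arr)
        assert opt.length == pytest.approx(4 * side)

    def test_rejects_above_cap(self):
        coords = {str(i): (i, i * i % 7) for i in range(10)}
        arr = tl.build_array("big", coords)
        with pytest.raises(ValueError, match="cap"):
            tl.optimal_open_path(arr)

    @pytest.mark.parametrize("name", ["double_trapezoid", "z_array", "pentagon"])
    def test_agrees_with_brute_force_oracle(self, name):
        arr = tl.get_array(name)
        _, oracle_len = brute_force_open_path(
            arr.labels, lambda a, b: arr.dist[arr.index_of(a), arr.index_of(b)]
        )
        assert tl.optimal_open_path(arr).length == pytest.approx(oracle_len)

    def test_any_full_route_at_least_optimal(self, double_trapezoid, rng):
        opt = tl.optimal_open_path(double_trapezoid).length
        labels = list(double_trapezoid.labels)
        for _ in range(50):
            seq = list(rng.permutation(labels)) + list(
                rng.choice(labels, size=3)
            )
            assert tl.route_distance(double_trapezoid, seq) >= opt - 1e-9

    @given(c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_scaling_scales_distances(self, c):
        arr = tl.build_array(
            "tri", {"A": (0, 0), "B": (1, 0), "C": (0.3, 0.9)}
        )
        scaled = arr.scaled(c)
        assert tl.optimal_open_path(scaled).length == pytest.approx(
            c * tl.optimal_open_path(arr).length
        )
        seq = ["A", "C", "A", "B"]
        assert tl.route_distance(scaled, seq) == pytest.approx(
            c * tl.route_distance(arr, seq)
        )
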