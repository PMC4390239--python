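import itertools
import math

import numpy as np
import pytest

from podnet.association import AnalysisError
from podnet.catalog import MarkGrade
from podnet.spatial import (
    Coastline,
    compare_area_group_sizes,
    compare_group_distances,
    distance_to_coast,
    haversine_km,
    load_coastline,
    mann_whitney_u,
)
from conftest import make_db


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((-10.0, 54.0), (-10.0, 54.0)) == 0.0

    def test_one_degree_along_equator(self):
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111.19, abs=0.01)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = (float(rng.uniform(-180, 180)), float(rng.uniform(-89, 89)))
            b = (float(rng.uniform(-180, 180)), float(rng.uniform(-89, 89)))
            assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((200.0, 0.0), (0.0, 0.0))


MERIDIAN = Coastline([[(0.0, -0.5), (0.0, 0.5)]])


class TestDistanceToCoast:
    def test_vertex_distance_is_zero(self):
        assert distance_to_coast((0.0, 0.5), MERIDIAN) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_offset_at_equator(self):
        assert distance_to_coast((0.1, 0.0), MERIDIAN) == pytest.approx(11.12, abs=0.05)

    def test_never_exceeds_any_vertex_distance(self):
        rng = np.random.default_rng(4)
        parts = [rng.uniform(-1, 1, size=(6, 2)) * [5, 3] + [-10, 54]]
        coast = Coastline(parts)
        for _ in range(25):
            pt = (float(rng.uniform(-16, -4)), float(rng.uniform(52, 56)))
            d = distance_to_coast(pt, coast)
            for part in coast.parts:
                for v in part:
                    assert d <= haversine_km(pt, tuple(v)) + 1e-6

    def test_agrees_with_dense_sampling_oracle(self):
        rng = np.random.default_rng(8)
        part = np.column_stack(
            [rng.uniform(-10.4, -9.6, 5), rng.uniform(53.8, 54.2, 5)]
        )
        coast = Coastline([part])
        for _ in range(5):
            pt = (float(rng.uniform(-10.6, -9.4)), float(rng.uniform(53.7, 54.3)))
            d = distance_to_coast(pt, coast)
            t = np.linspace(0, 1, 10_000)[:, None]
            dense = min(
                haversine_km(pt, (float(p[0]), float(p[1])))
                for a, b in zip(part[:-1], part[1:])
                for p in (a + t * (b - a))
            )
            assert d == pytest.approx(dense, rel=0.005)

    def test_empty_coastline_rejected(self):
        with pytest.raises(ValueError):
            distance_to_coast((0.0, 0.0), Coastline([]))

    def test_geojson_and_csv_loaders(self, tmp_path):
        gj = tmp_path / "coast.geojson"
        gj.write_text(
            '{"type": "LineString", "coordinates": [[-10.0, 54.0], [-10.0, 54.5]]}'
        )
        c1 = load_coastline(gj)
        csvf = tmp_path / "coast.csv"
        csvf.write_text("lon,lat\n-10.0,54.0\n-10.0,54.5\n")
        c2 = load_coastline(csvf)
        assert np.allclose(c1.parts[0], c2.parts[0])


def brute_force_two_sided_p(x, y):
    """Exact two-sided p by enumerating all labelings of the pooled sample."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert r.u == 9 and r.n1 == r.n2 == 3
        assert r.method == "exact"

    def test_single_tied_pair(self):
        r = mann_whitney_u([1.0], [1.0])
        assert r.u == 0.5
        assert r.method == "normal-approximation"

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            r = mann_whitney_u(x, y, method="exact")
            assert r.p == pytest.approx(brute_force_two_sided_p(x, y), abs=1e-12)

    def test_u_plus_mirror_u_is_n1_n2(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.integers(0, 6, size=int(rng.integers(1, 10))).astype(float)
            y = rng.integers(0, 6, size=int(rng.integers(1, 10))).astype(float)
            u1 = mann_whitney_u(x, y, method="normal").u
            u2 = mann_whitney_u(y, x, method="normal").u
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_exact_and_normal_agree_for_moderate_samples(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            pooled = rng.permutation(np.arange(1.0, 19.0))
            x, y = pooled[:9], pooled[9:]
            pe = mann_whitney_u(x, y, method="exact").p
            pn = mann_whitney_u(x, y, method="normal").p
            assert abs(pe - pn) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestGroupComparisons:
    @staticmethod
    def _partitioned_db():
        from podnet.association import association_matrix
        from podnet.community import build_sociogram, detect_communities

        db = make_db(
            [["a1", "a2"], ["a1", "a3"], ["a2", "a3"], ["b1", "b2"]],
            distances=[0.3, 0.8, 1.2, 20.0],
        )
        m = association_matrix(db, grade_filter={MarkGrade.PERMANENT})
        p = detect_communities(build_sociogram(m, db))
        return db, p

    def test_complete_separation_gives_max_u(self):
        db, p = self._partitioned_db()
        summary, test = compare_group_distances(db, p, {"A": {"A"}, "B": {"B"}})
        assert test.u == test.n1 * test.n2
        assert summary.groups["A"]["max"] < summary.groups["B"]["min"]
        assert summary.groups["A"]["min"] <= summary.groups["A"]["q1"] <= summary.groups["A"]["median"]

    def test_missing_distances_counted_not_crashed(self):
        db, p = self._partitioned_db()
        db.encounters[0].distance_from_shore_km = None
        summary, _ = compare_group_distances(db, p, {"A": {"A"}, "B": {"B"}})
        assert summary.n_excluded_missing == 1
        assert summary.groups["A"]["n"] == 2

    def test_side_without_encounters_raises(self):
        db, p = self._partitioned_db()
        with pytest.raises(AnalysisError):
            compare_group_distances(db, p, {"A": {"A"}, "Z": {"Z"}})

    def test_synthetic_inshore_offshore_separation(self, default_db):
        from podnet.association import association_matrix
        from podnet.community import assign_unmarked, build_sociogram, detect_communities

        db, _ = default_db
        m = association_matrix(db, grade_filter={MarkGrade.PERMANENT})
        p = assign_unmarked(db, detect_communities(build_sociogram(m, db)))
        labels = p.labels
        grouping = {"A": {labels[0]}, "B-E": set(labels[1:])}
        summary, test = compare_group_distances(db, p, grouping)
        assert summary.groups["A"]["mean"] < 1.0
        assert summary.groups["B-E"]["mean"] > 4.0
        assert test.u == test.n1 * test.n2  # complete separation by construction

    def test_area_group_size_comparison(self, default_db):
        db, _ = default_db
        r = compare_area_group_sizes(db, "MAYO", "CONNEMARA")
        assert r.n1 + r.n2 == db.n_encounters
        assert 0 <= r.p <= 1
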