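"""Haversine geometry, window building and masked partial Mantel tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleodrift.spacetime import (
    bootstrap_ci,
    build_windows,
    haversine,
    haversine_matrix,
    hull_area_km2,
    partial_mantel,
)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine(48.2, 16.4, 48.2, 16.4) == 0.0

    def test_half_and_quarter_circumference(self):
        assert haversine(0, 0, 0, 179.9999999) == pytest.approx(
            np.pi * 6371.0088, abs=0.1
        )
        assert haversine(0, 0, 90, 0) == pytest.approx(np.pi * 6371.0088 / 2, abs=0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-89, 89), st.floats(-179, 179)
            ),
            min_size=3, max_size=3,
        )
    )
    def test_symmetry_and_triangle_inequality(self, pts):
        (a, b, c) = pts
        dab = haversine(*a, *b)
        dba = haversine(*b, *a)
        assert dab == pytest.approx(dba, abs=1e-9)
        dac = haversine(*a, *c)
        dcb = haversine(*c, *b)
        assert dab <= dac + dcb + 1e-9

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError):
            haversine(91, 0, 0, 0)


class TestHullArea:
    def test_degenerate_point_sets(self):
        assert hull_area_km2(np.array([10.0]), np.array([10.0])) == 0.0
        # points on one meridian project exactly collinear
        assert hull_area_km2(np.array([10.0, 11.0, 12.0]), np.array([5.0, 5.0, 5.0])) == 0.0
        # points on one parallel are only near-degenerate (the parallel curves)
        area = hull_area_km2(np.array([10.0, 10.0, 10.0]), np.array([1.0, 2.0, 3.0]))
        assert area < 1e-3 * (2 * 111.0) ** 2

    def test_small_square_near_equator(self):
        # 1 degree x 1 degree at the equator ~ 111.32^2 km^2
        lat = np.array([0.0, 0.0, 1.0, 1.0])
        lon = np.array([0.0, 1.0, 0.0, 1.0])
        area = hull_area_km2(lat, lon)
        assert area == pytest.approx(111.19**2, rel=0.01)


def staged_meta():
    """15 samples: 5 old clustered, 10 younger spread over the full area."""
    rows = []
    for i in range(5):
        rows.append({"id": f"old{i}", "age_BP": 8000 - 10 * i, "lat": 50.0 + 0.01 * i, "lon": 10.0})
    corners = [(40, 0), (60, 0), (40, 40), (60, 40), (50, 20)]
    for i in range(10):
        la, lo = corners[i % 5]
        rows.append({"id": f"new{i}", "age_BP": 5000 - 100 * i, "lat": la + 0.1 * i, "lon": lo + 0.1 * i})
    return pd.DataFrame(rows)


class TestWindows:
    def test_single_window_when_coeval_and_spread(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(12)],
                "age_BP": 3000.0,
                "lat": rng.uniform(40, 60, 12),
                "lon": rng.uniform(0, 40, 12),
            }
        )
        ws = build_windows(meta)
        assert len(ws) == 1
        assert len(ws.windows[0].member_ids) == 12
        assert ws.windows[0].mean_age == 3000.0

    def test_too_few_samples_rejected(self):
        meta = staged_meta().iloc[:9]
        with pytest.raises(ValueError, match="at least"):
            build_windows(meta)

    def test_staged_fixture_membership_matches_hand_enumeration(self):
        meta = staged_meta()
        ws = build_windows(meta, step_years=250, min_n=10, area_fraction=2 / 3)
        # oldest window must broaden past the 5 clustered old samples and
        # pull in young spread samples until the hull covers 2/3 of the total
        first = ws.windows[0]
        assert first.start_age == 8000
        assert set(first.member_ids) >= {f"old{i}" for i in range(5)}
        assert len(first.member_ids) >= 10
        assert first.area_km2 >= (2 / 3) * ws.total_area_km2

    def test_lowering_min_n_never_removes_windows(self):
        meta = staged_meta()
        strict = build_windows(meta, min_n=12)
        relaxed = build_windows(meta, min_n=10)
        assert {w.start_age for w in strict.windows} <= {w.start_age for w in relaxed.windows}


def random_symmetric(rng, n, scale=1.0):
    m = rng.uniform(0, scale, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestPartialMantel:
    def test_perfect_association(self):
        rng = np.random.default_rng(1)
        geo = random_symmetric(rng, 15, 2000)
        tim = random_symmetric(rng, 15, 2000)
        gen = geo * 1e-5
        res = partial_mantel(gen, geo, tim, mask_km=0, mask_years=0, n_perm=99, seed=0)
        assert res.r > 0.99
        assert res.p_value <= 0.05

    def test_all_false_mask_equals_unmasked(self):
        rng = np.random.default_rng(2)
        gen = random_symmetric(rng, 12)
        geo = random_symmetric(rng, 12, 2000)
        tim = random_symmetric(rng, 12, 2000)
        r_masked = partial_mantel(gen, geo, tim, mask_km=0, mask_years=0, n_perm=0, seed=0).r
        # manual partial correlation over all upper-triangle pairs
        iu, ju = np.triu_indices(12, 1)
        g, x, t = gen[iu, ju], geo[iu, ju], tim[iu, ju]

        def resid(y, t):
            X = np.column_stack([np.ones_like(t), t])
            return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

        rg, rx = resid(g, t), resid(x, t)
        r_plain = float(np.corrcoef(rg, rx)[0, 1])
        assert r_masked == pytest.approx(r_plain, abs=1e-12)

    def test_masking_reduces_pair_count(self):
        rng = np.random.default_rng(3)
        gen = random_symmetric(rng, 12)
        geo = random_symmetric(rng, 12, 1000)
        tim = random_symmetric(rng, 12, 1000)
        full = partial_mantel(gen, geo, tim, mask_km=0, mask_years=0, n_perm=0, seed=0)
        masked = partial_mantel(gen, geo, tim, mask_km=500, mask_years=500, n_perm=0, seed=0)
        assert masked.n_pairs <= full.n_pairs

    def test_too_few_unmasked_pairs_rejected(self):
        rng = np.random.default_rng(4)
        gen = random_symmetric(rng, 6)
        geo = random_symmetric(rng, 6, 100)  # everything closer than 500 km
        tim = random_symmetric(rng, 6, 100)
        with pytest.raises(ValueError, match="unmasked"):
            partial_mantel(gen, geo, tim)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        gen = random_symmetric(rng, 12)
        geo = random_symmetric(rng, 12, 2000)
        tim = random_symmetric(rng, 12, 2000)
        a = partial_mantel(gen, geo, tim, mask_km=0, mask_years=0, n_perm=199, seed=7)
        b = partial_mantel(gen, geo, tim, mask_km=0, mask_years=0, n_perm=199, seed=7)
        assert a.p_value == b.p_value


class TestBootstrap:
    def _matrices(self, n=14, seed=6):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(35, 60, n)
        lon = rng.uniform(-5, 40, n)
        geo = haversine_matrix(lat, lon)
        ages = rng.uniform(2000, 9000, n)
        tim = np.abs(ages[:, None] - ages[None, :])
        gen = geo * 1e-5  # noise-free isolation by distance
        ids = [f"s{i}" for i in range(n)]
        return ids, gen, geo, tim

    def test_tight_interval_around_perfect_signal(self):
        ids, gen, geo, tim = self._matrices()
        lo, hi, redrawn = bootstrap_ci(ids, gen, geo, tim, n_boot=100, seed=1, mask_km=0, mask_years=0)
        assert hi - lo < 0.05
        assert lo > 0.9

    def test_single_resample_degenerate_interval(self):
        ids, gen, geo, tim = self._matrices(seed=7)
        lo, hi, _ = bootstrap_ci(ids, gen, geo, tim, n_boot=1, seed=2, mask_km=0, mask_years=0)
        assert lo == hi
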