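"""Spatiotemporal isolation-by-distance machinery.

Great-circle distances, sliding time windows broadened forward in time
under a joint sample-count / area-coverage rule, and masked partial Mantel
tests with permutation p-values and individual-resampling bootstrap
confidence intervals.  The masking removes pairs of samples that are both
geographically close (< ``mask_km``) and near-contemporaneous
(< ``mask_years``), so the test measures isolation by distance *between*
demes rather than within them, and the partial correlation conditions on
the temporal distance to correct for age variation inside a window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

EARTH_RADIUS_KM = 6371.0088


def haversine(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon < 180.0 + 1e-9:
            raise ValueError(f"longitude {lon} outside [-180, 180)")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = min(1.0, a)
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    n = len(lat)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = haversine(lat[i], lon[i], lat[j], lon[j])
    return D


def hull_area_km2(lat: np.ndarray, lon: np.ndarray) -> float:
    """Convex-hull area of a set of points, in km^2.

    Points are projected with a Lambert azimuthal equal-area projection
    about their centroid before taking the planar hull; adequate at
    continental scale.  Fewer than three distinct points give area 0.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 3:
        return 0.0
    phi = np.radians(lat)
    lam = np.radians(lon)
    phi0 = np.mean(phi)
    lam0 = np.arctan2(np.mean(np.sin(lam)), np.mean(np.cos(lam)))
    # Lambert azimuthal equal-area centered at (phi0, lam0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    denom = np.maximum(denom, 1e-12)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    pts = np.column_stack([x, y])
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is area
    except QhullError:
        return 0.0  # collinear or degenerate


@dataclass
class TimeWindow:
    start_age: float
    member_ids: list[str]
    mean_age: float
    area_km2: float


@dataclass
class WindowSeries:
    windows: list[TimeWindow]
    dropped_starts: list[float] = field(default_factory=list)
    total_area_km2: float = 0.0

    def __len__(self) -> int:
        return len(self.windows)


def build_windows(
    meta: pd.DataFrame,
    step_years: float = 250.0,
    min_n: int = 10,
    area_fraction: float = 2.0 / 3.0,
) -> WindowSeries:
    """Sliding windows broadened forward in time.

    Window start ages descend in ``step_years`` steps from the oldest
    sample.  Each window accumulates samples forward in time (decreasing
    age BP) until it holds at least ``min_n`` members whose convex hull
    covers at least ``area_fraction`` of the hull of *all* samples in
    ``meta``.  The window age is the mean member age.  Start ages at the
    recent end whose windows can never satisfy both criteria are dropped
    and reported.
    """
    required = {"id", "age_BP", "lat", "lon"}
    if required - set(meta.columns):
        raise ValueError(f"meta must have columns {sorted(required)}")
    if len(meta) < min_n:
        raise ValueError(f"need at least {min_n} samples, got {len(meta)}")
    total_area = hull_area_km2(meta["lat"].to_numpy(), meta["lon"].to_numpy())
    order = meta.sort_values("age_BP", ascending=False, kind="stable").reset_index(drop=True)
    ages = order["age_BP"].to_numpy()

    windows: list[TimeWindow] = []
    dropped: list[float] = []
    start = float(ages.max())
    min_age = float(ages.min())
    while start >= min_age:
        cand = order[order["age_BP"] <= start]
        # broaden by distinct age boundaries: samples of equal age enter
        # the window together
        bounds = sorted(cand["age_BP"].unique(), reverse=True)
        found = None
        for b in bounds:
            sub = cand[cand["age_BP"] >= b]
            if len(sub) < min_n:
                continue
            area = hull_area_km2(sub["lat"].to_numpy(), sub["lon"].to_numpy())
            if area >= area_fraction * total_area:
                found = (sub, area)
                break
        if found is None:
            dropped.append(start)
        else:
            sub, area = found
            windows.append(
                TimeWindow(
                    start_age=start,
                    member_ids=[str(s) for s in sub["id"]],
                    mean_age=float(sub["age_BP"].mean()),
                    area_km2=area,
                )
            )
        start -= step_years
    return WindowSeries(windows, dropped, total_area)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_pairs: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    mean_age: float = np.nan


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, x]."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return np.nan
    return float((a * b).sum() / denom)


def partial_mantel(
    genD: np.ndarray,
    geoD: np.ndarray,
    timeD: np.ndarray,
    mask_km: float = 500.0,
    mask_years: float = 500.0,
    n_perm: int = 999,
    seed: int = 0,
    min_pairs: int = 10,
    permute_residuals: bool = False,
) -> MantelResult:
    """Masked partial Mantel test: corr(gen, geo | time).

    Pairs with geographic distance < ``mask_km`` AND temporal distance <
    ``mask_years`` are masked out of all three matrices.  The partial
    correlation uses the residual-matrix method over unmasked upper-triangle
    entries; the p-value permutes sample labels of the genetic matrix
    (``permute_residuals`` switches to permutation of its residual vector):
    ``p = (1 + #{|r*| >= |r|}) / (1 + n_perm)``.  Deterministic given seed.
    """
    genD = np.asarray(genD, dtype=float)
    geoD = np.asarray(geoD, dtype=float)
    timeD = np.asarray(timeD, dtype=float)
    n = genD.shape[0]
    if genD.shape != (n, n) or geoD.shape != (n, n) or timeD.shape != (n, n):
        raise ValueError("matrices must be congruent and square")
    iu, ju = np.triu_indices(n, k=1)
    unmasked = ~((geoD[iu, ju] < mask_km) & (timeD[iu, ju] < mask_years))
    if unmasked.sum() < min_pairs:
        raise ValueError(f"only {int(unmasked.sum())} unmasked pairs; need >= {min_pairs}")
    ii, jj = iu[unmasked], ju[unmasked]
    g = genD[ii, jj]
    x = geoD[ii, jj]
    t = timeD[ii, jj]
    rx = _residualize(x, t)
    rg = _residualize(g, t)
    r_obs = _pearson(rg, rx)

    # fixed projection for the repeated residualizations under permutation
    X = np.column_stack([np.ones_like(t), t])
    G = np.linalg.solve(X.T @ X, X.T)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if permute_residuals:
            rg_p = rng.permutation(rg)
        else:
            perm = rng.permutation(n)
            g_p = genD[perm[ii], perm[jj]]
            rg_p = g_p - X @ (G @ g_p)
        r_p = _pearson(rg_p, rx)
        if np.isfinite(r_p) and abs(r_p) >= abs(r_obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_pairs=int(unmasked.sum()))


def bootstrap_ci(
    ids: list[str],
    genD: np.ndarray,
    geoD: np.ndarray,
    timeD: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    mask_km: float = 500.0,
    mask_years: float = 500.0,
    min_pairs: int = 10,
    max_redraws: int = 100,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for the masked partial Mantel r.

    Resamples individuals with replacement, rebuilds the three matrices on
    the resample and recomputes r (no permutations).  Degenerate resamples
    (too few unmasked pairs or undefined correlation) are redrawn and
    counted; returns ``(low, high, n_redrawn)``.
    """
    n = len(ids)
    rng = np.random.default_rng(seed)
    stats = []
    redrawn = 0
    while len(stats) < n_boot:
        idx = rng.integers(n, size=n)
        gD = genD[np.ix_(idx, idx)]
        xD = geoD[np.ix_(idx, idx)]
        tD = timeD[np.ix_(idx, idx)]
        try:
            res = partial_mantel(
                gD, xD, tD, mask_km=mask_km, mask_years=mask_years,
                n_perm=0, seed=0, min_pairs=min_pairs,
            )
            r = res.r
        except ValueError:
            r = np.nan
        if not np.isfinite(r):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        stats.append(r)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi), redrawn


def window_mantel_series(
    meta: pd.DataFrame,
    genD: pd.DataFrame,
    windows: WindowSeries,
    n_perm: int = 999,
    n_boot: int = 0,
    seed: int = 0,
    mask_km: float = 500.0,
    mask_years: float = 500.0,
) -> pd.DataFrame:
    """Per-window masked partial Mantel r/p (and bootstrap CI when n_boot > 0).

    ``genD`` is a labelled genetic distance matrix covering the window
    members; geographic and temporal distances are built from ``meta``.
    """
    meta = meta.set_index("id")
    rows = []
    rng = np.random.default_rng(seed)
    for w in windows.windows:
        ids = w.member_ids
        sub = meta.loc[ids]
        geo = haversine_matrix(sub["lat"].to_numpy(), sub["lon"].to_numpy())
        ages = sub["age_BP"].to_numpy()
        tim = np.abs(ages[:, None] - ages[None, :])
        g = genD.loc[ids, ids].to_numpy()
        try:
            res = partial_mantel(
                g, geo, tim, mask_km=mask_km, mask_years=mask_years,
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
        except ValueError:
            continue
        row = {
            "mean_age": w.mean_age,
            "r": res.r,
            "p": res.p_value,
            "n_pairs": res.n_pairs,
            "n_members": len(ids),
        }
        if n_boot > 0:
            lo, hi, _ = bootstrap_ci(
                ids, g, geo, tim, n_boot=n_boot, seed=int(rng.integers(2**31)),
                mask_km=mask_km, mask_years=mask_years,
            )
            row["ci_low"], row["ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
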