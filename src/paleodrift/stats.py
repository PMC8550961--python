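"""Core population-genetic statistics on pseudo-haploid call matrices.

f4-statistics with block-jackknife standard errors, outgroup coancestry
(the shared-drift matrix that feeds the ancestry mixture model and MDS),
raw pairwise mismatch distances, and Weir-Cockerham FST in its haploid
allele-count form.

All estimators average per-site quantities over pairwise- (or
quadruple-) complete observations; missing calls never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, CallMatrix


@dataclass
class DistanceMatrix:
    """Symmetric mismatch-proportion matrix with per-pair site counts."""

    values: np.ndarray  # N x N, NaN where no shared sites
    counts: np.ndarray  # N x N shared non-missing sites
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_distances(calls: CallMatrix) -> DistanceMatrix:
    """Average allele mismatch over pairwise-complete sites.

    ``d_ij = mean over shared sites of (call_i - call_j)^2`` — for 0/1
    calls this is the mismatch proportion.  Pairs with zero shared sites
    get NaN.
    """
    X = calls.data.astype(float)
    obs = calls.observed().astype(float)
    X0 = np.where(calls.observed(), X, 0.0)
    counts = obs @ obs.T
    # mismatches = sum x_i(1-x_j) + (1-x_i)x_j over shared sites
    agree11 = X0 @ X0.T
    agree00 = ((1.0 - X0) * obs) @ ((1.0 - X0) * obs).T
    mism = counts - agree11 - agree00
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, mism / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, counts.astype(np.int64), list(calls.samples))


@dataclass
class F4Result:
    labels: tuple[str, str, str, str]
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    degenerate: bool = False  # A == B or C == D


def _freq_rows(source, labels) -> tuple[np.ndarray, np.ndarray]:
    """Resolve labels to per-site frequencies + validity.

    ``source`` is either a CallMatrix (labels are sample ids; each sample's
    0/1 call is its frequency) or a DataFrame of per-population frequencies
    (always valid).
    """
    if isinstance(source, CallMatrix):
        rows = np.array([source.row(l) for l in labels], dtype=float)
        valid = rows != MISSING
        return rows, valid
    freqs = np.array([np.asarray(source[l], dtype=float) for l in labels])
    return freqs, np.isfinite(freqs)


def _block_jackknife(num: np.ndarray, n_blocks: int) -> tuple[float, float, int]:
    """Delete-one jackknife of a per-site mean over contiguous equal-count blocks."""
    S = len(num)
    est = float(num.mean())
    n_blocks = min(n_blocks, S)
    if n_blocks < 2:
        return est, np.nan, n_blocks
    blocks = np.array_split(num, n_blocks)
    total = num.sum()
    loo = np.array([(total - b.sum()) / (S - len(b)) for b in blocks])
    mean_loo = loo.mean()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - mean_loo) ** 2)))
    return est, se, n_blocks


def f4(
    source,
    a: str,
    b: str,
    c: str,
    d: str,
    n_blocks: int = 100,
) -> F4Result:
    """f4(A,B;C,D) = mean over usable sites of (p_A - p_B)(p_C - p_D).

    ``source`` may be a :class:`CallMatrix` (labels name samples, whose
    pseudo-haploid calls serve as frequencies) or a per-population
    frequency table.  Usable sites have data in all four labels.  The
    standard error comes from a delete-one block jackknife over
    ``n_blocks`` contiguous equal-count site blocks; ``Z = estimate / SE``.
    """
    degenerate = (a == b) or (c == d)
    rows, valid = _freq_rows(source, [a, b, c, d])
    usable = valid.all(axis=0)
    S = int(usable.sum())
    if S == 0:
        raise ValueError("no site has data in all four labels")
    p = rows[:, usable]
    num = (p[0] - p[1]) * (p[2] - p[3])
    est, se, nb = _block_jackknife(num, n_blocks)
    z = est / se if se and np.isfinite(se) and se > 0 else np.nan
    return F4Result((a, b, c, d), est, se, z, S, nb, degenerate)


@dataclass
class CoancestryMatrix:
    """Pairwise shared drift relative to an outgroup.

    ``c_ij = mean over shared sites of (p_i - p_O)(p_j - p_O)``; the
    diagonal is not directly estimable from single pseudo-haploid genomes
    and is set by policy ("row-max" imputation or NaN for "exclude").
    """

    values: np.ndarray
    labels: list[str]
    outgroup: str
    diagonal_policy: str = "row-max"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def coancestry(
    calls: CallMatrix, outgroup_label: str, diagonal: str = "row-max"
) -> CoancestryMatrix:
    """Outgroup coancestry matrix over all non-outgroup samples.

    Exactly equals ``f4(i, O; j, O)`` computed on the same shared-site set
    (sites non-missing in i, j and the outgroup).
    """
    if outgroup_label not in calls.samples:
        raise ValueError(f"outgroup {outgroup_label!r} not in panel")
    if diagonal not in ("row-max", "exclude"):
        raise ValueError("diagonal policy must be 'row-max' or 'exclude'")
    o = calls.row(outgroup_label).astype(float)
    o_obs = o != MISSING
    others = [s for s in calls.samples if s != outgroup_label]
    X = np.array([calls.row(s) for s in others], dtype=float)
    obs = (X != MISSING) & o_obs[None, :]
    Y = np.where(obs, X - o, 0.0)
    counts = obs.astype(float) @ obs.astype(float).T
    if np.any(counts[~np.eye(len(others), dtype=bool)] == 0):
        raise ValueError("some pair shares no site with outgroup data")
    values = (Y @ Y.T) / counts
    if diagonal == "row-max":
        n = len(others)
        off = values.copy()
        np.fill_diagonal(off, -np.inf)
        np.fill_diagonal(values, off.max(axis=1))
    else:
        np.fill_diagonal(values, np.nan)
    return CoancestryMatrix(values, others, outgroup_label, diagonal)


@dataclass
class FstResult:
    fst: float  # genome-wide ratio of averages
    per_site_num: np.ndarray  # between-group variance component a
    per_site_den: np.ndarray  # a + within-group mean square
    n_skipped: int  # monomorphic or under-covered sites

    @property
    def per_site(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.per_site_num / self.per_site_den


def wc_fst(calls: CallMatrix, group1: list[str], group2: list[str]) -> FstResult:
    """Weir-Cockerham FST between two groups, haploid allele-count form.

    Each pseudo-haploid individual contributes one allele.  Per site, a
    one-way ANOVA over the two groups yields the between-group variance
    component ``a = (MSB - MSW) / n_c`` and the denominator ``a + MSW``;
    the genome-wide value is the ratio of summed numerators to summed
    denominators.  Sites monomorphic across both groups, or with fewer
    than two observed alleles in either group, are skipped and counted.
    Per-site values may be negative and are not truncated.
    """
    X1 = np.array([calls.row(s) for s in group1], dtype=float)
    X2 = np.array([calls.row(s) for s in group2], dtype=float)
    obs1, obs2 = X1 != MISSING, X2 != MISSING
    n1 = obs1.sum(axis=0).astype(float)
    n2 = obs2.sum(axis=0).astype(float)
    c1 = np.where(obs1, X1, 0.0).sum(axis=0)
    c2 = np.where(obs2, X2, 0.0).sum(axis=0)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, c1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(ok, c2 / np.maximum(n2, 1), np.nan)
    N = n1 + n2
    pbar = (c1 + c2) / np.maximum(N, 1)
    poly = ok & (pbar > 0) & (pbar < 1)

    r = 2.0
    ssb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msb = ssb / (r - 1.0)
    ssw = n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        msw = np.where(N > r, ssw / (N - r), np.nan)
        nc = (N - (n1**2 + n2**2) / np.maximum(N, 1)) / (r - 1.0)
        a = (msb - msw) / nc
    den = a + msw
    num = np.where(poly, a, np.nan)
    den = np.where(poly, den, np.nan)
    n_skipped = int(calls.n_sites - poly.sum())
    fst = float(np.nansum(num) / np.nansum(den)) if np.nansum(np.abs(den)) > 0 else np.nan
    return FstResult(fst, num, den, n_skipped)
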