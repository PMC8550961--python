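"""Independent brute-force oracles used to validate the vectorized estimators.

Everything here is deliberately written with explicit Python loops and the
defining formulas, independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def oracle_pairwise_distance(row_i, row_j):
    """Mean squared difference over shared non-missing sites (None if none)."""
    num = 0.0
    n = 0
    for a, b in zip(row_i, row_j):
        if a != MISSING and b != MISSING:
            num += float(a - b) ** 2
            n += 1
    return (num / n, n) if n else (None, 0)


def oracle_f4(pa, pb, pc, pd):
    """Mean of (pA-pB)(pC-pD) over sites where all four have data."""
    vals = []
    for a, b, c, d in zip(pa, pb, pc, pd):
        if MISSING in (a, b, c, d):
            continue
        vals.append(float(a - b) * float(c - d))
    return sum(vals) / len(vals)


def oracle_coancestry(row_i, row_j, row_o):
    """Mean of (x_i - x_O)(x_j - x_O) over triple-complete sites."""
    vals = []
    for a, b, o in zip(row_i, row_j, row_o):
        if MISSING in (a, b, o):
            continue
        vals.append(float(a - o) * float(b - o))
    return sum(vals) / len(vals)


def oracle_wc_fst_site(calls_g1, calls_g2):
    """Weir-Cockerham variance components for one site, haploid form.

    Returns (a, a + msw) or None when the site is unscorable (fewer than
    two observed alleles in a group, or monomorphic overall).
    """
    obs1 = [x for x in calls_g1 if x != MISSING]
    obs2 = [x for x in calls_g2 if x != MISSING]
    n1, n2 = len(obs1), len(obs2)
    if n1 < 2 or n2 < 2:
        return None
    p1 = sum(obs1) / n1
    p2 = sum(obs2) / n2
    N = n1 + n2
    pbar = (sum(obs1) + sum(obs2)) / N
    if pbar <= 0.0 or pbar >= 1.0:
        return None
    r = 2
    msb = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    ssw = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
    msw = ssw / (N - r)
    nc = (N - (n1**2 + n2**2) / N) / (r - 1)
    a = (msb - msw) / nc
    return a, a + msw


def oracle_wc_fst(data, idx1, idx2):
    """Genome-wide ratio-of-averages FST over all scorable sites."""
    num = 0.0
    den = 0.0
    for s in range(data.shape[1]):
        out = oracle_wc_fst_site(
            [int(data[i, s]) for i in idx1], [int(data[i, s]) for i in idx2]
        )
        if out is None:
            continue
        num += out[0]
        den += out[1]
    return num / den


def oracle_r2(col_i, col_j, min_shared=20):
    shared = [(a, b) for a, b in zip(col_i, col_j) if a != MISSING and b != MISSING]
    if len(shared) < min_shared:
        return None
    xs = [float(a) for a, _ in shared]
    ys = [float(b) for _, b in shared]
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    if vx == 0 or vy == 0:
        return 0.0
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return cov * cov / (vx * vy)


def oracle_ld_prune(data, window=50, step=10, r2_max=0.2, min_shared=20):
    """Greedy window pruning re-implemented from the definition."""
    S = data.shape[1]
    if window < 2 or S < 2:
        return list(range(S))
    removed = set()
    start = 0
    while True:
        end = min(start + window, S)
        live = [i for i in range(start, end) if i not in removed]
        for ai in range(len(live)):
            i = live[ai]
            if i in removed:
                continue
            for bi in range(ai + 1, len(live)):
                j = live[bi]
                if j in removed:
                    continue
                r2 = oracle_r2(list(data[:, i]), list(data[:, j]), min_shared)
                if r2 is not None and r2 > r2_max:
                    removed.add(j)
        if end >= S:
            break
        start += step
    return [i for i in range(S) if i not in removed]


def oracle_balding_nichols_moments(p, F, n_draws, seed):
    """Monte-Carlo mean/variance of one Balding-Nichols step."""
    rng = np.random.default_rng(seed)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    draws = rng.beta(a, b, size=n_draws)
    return float(draws.mean()), float(draws.var())


def oracle_continuity_site_mc(y, derived, total, t1, t2, n_draws, seed):
    """Monte-Carlo estimate of one site's read-count likelihood.

    Simulates the model forward: x ~ Uniform(0,1) prior re-weighted by the
    forward kernel BN(y | x, t1) via importance sampling, z ~ BN(x, t2),
    g ~ Binomial(2, z), reads ~ Binomial(total, g/2).
    """
    from scipy.stats import beta as beta_dist, binom

    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n_draws)
    if t1 > 1e-9:
        scale = (1 - t1) / t1
        w = beta_dist.pdf(y, x * scale, (1 - x) * scale)
    else:
        x = np.full(n_draws, y)
        w = np.ones(n_draws)
    if t2 > 1e-9:
        scale2 = (1 - t2) / t2
        with np.errstate(invalid="ignore"):
            z = rng.beta(np.maximum(x, 1e-12) * scale2, np.maximum(1 - x, 1e-12) * scale2)
        z = np.where((x <= 0) | (x >= 1), x, z)
    else:
        z = x
    g = rng.binomial(2, np.clip(z, 0, 1))
    lik = binom.pmf(derived, total, g / 2.0)
    return float(np.sum(w * lik) / np.sum(w))
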