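"""Direct-ancestry (genetic continuity) test for ancient specimens.

Given exact derived-allele frequencies ``y`` in a target population and
read counts for an ancient specimen, the test compares two placements of
the specimen: on a direct line of ancestry to the target (null, the
specimen's branch drift ``t2 = 0``) versus as a sister group (``t2 > 0``).

Model per conditioned site: the target frequency ``y`` descends from an
ancestral frequency ``x`` through a Balding-Nichols drift step of
magnitude ``t1`` (``y | x`` is Beta with mean ``x`` and variance
``t1 * x * (1 - x)``), so conditioning on the observed ``y`` gives the
reversed-time ancestor distribution ``f(x | y, t1) \\propto
BN(y | x, t1) * pi(x)`` with a uniform prior ``pi`` on the ancestral
frequency.  The direction of this conditional matters: the forward and
reversed Balding-Nichols kernels differ in shape, and that asymmetry is
what separates drift on the target branch (``t1``) from drift private to
the specimen (``t2``) — a symmetric approximation with mean ``y`` would
make the likelihood depend on ``(t1, t2)`` only through the total drift
and leave the test degenerate.  The specimen's population frequency ``z``
drifts forward from ``x`` by ``t2``; its diploid genotype is
Binomial(2, z) and each of its ``n`` reads is derived with probability
``g/2`` (optionally perturbed by a known sequencing error rate).  Because
the read likelihood given the genotype depends on ``z`` only through its
first two moments, the forward drift integral is available in closed form
and a single fixed-order Gauss-Legendre quadrature over ``x`` evaluates
the site likelihood.

The likelihood-ratio statistic ``2 (LL_full - LL_null)`` is referred to
the boundary-corrected null ``1/2 chi2_0 + 1/2 chi2_1`` since ``t2 = 0``
lies on the parameter boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .panel import CallMatrix, ReadCounts, filter_sites, ld_prune

_T_MIN = 1e-9  # below this, a drift step is treated as exact identity
_T_MAX = 0.99


@dataclass
class ContinuityInput:
    """Conditioned sites for one specimen: target frequency + read counts."""

    y: np.ndarray  # target derived-allele frequency, strictly in (0, 1)
    derived: np.ndarray
    total: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.derived = np.asarray(self.derived, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if np.any((self.y <= 0.0) | (self.y >= 1.0)):
            raise ValueError("target frequencies must be strictly inside (0, 1)")
        if np.any(self.derived < 0) or np.any(self.derived > self.total):
            raise ValueError("need 0 <= derived <= total")
        if np.any(self.total < 1):
            raise ValueError("every site needs at least one read")

    @property
    def n_sites(self) -> int:
        return len(self.y)


@dataclass
class ContinuityResult:
    t1_hat: float
    t2_hat: float
    ll_full: float
    ll_null: float
    lrt: float
    p_value: float
    n_sites: int
    provenance: dict = field(default_factory=dict)


def condition_sites(
    target: CallMatrix,
    reads: ReadCounts,
    sample: str,
    min_coverage_fraction: float = 0.75,
    min_minor_count: int = 2,
    transversions_only: bool = True,
    prune: bool = True,
    min_sites: int = 100,
) -> ContinuityInput:
    """Apply the conditioning filters and build the test input.

    Keeps target-panel sites that are transversions, segregate at least as
    ``min_minor_count``-tons among target samples, are covered in at least
    ``min_coverage_fraction`` of them, survive LD pruning (50/10/0.2), and
    at which the specimen has at least one read.  The target frequency
    ``y`` is the derived fraction among non-missing target calls; sites
    fixed in the target are excluded by construction of the doubleton
    filter (and re-checked).
    """
    filtered, kept_idx = filter_sites(
        target,
        transversions_only=transversions_only,
        min_coverage_fraction=min_coverage_fraction,
        min_minor_count=min_minor_count,
    )
    ledger = {
        "n_input_sites": target.n_sites,
        "n_after_filters": filtered.n_sites,
    }
    if prune:
        keep = ld_prune(filtered)
        filtered = filtered.take_sites(keep)
        kept_idx = kept_idx[keep]
        ledger["n_after_pruning"] = filtered.n_sites
    der_row, tot_row = reads.row(sample)
    der_row, tot_row = der_row[kept_idx], tot_row[kept_idx]
    obs = filtered.observed()
    n_obs = obs.sum(axis=0)
    n_der = np.where(obs, filtered.data == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = n_der / np.maximum(n_obs, 1)
    ok = (tot_row >= 1) & (n_obs > 0) & (y > 0.0) & (y < 1.0)
    ledger["n_with_reads_and_segregating"] = int(ok.sum())
    if ok.sum() < min_sites:
        raise ValueError(
            f"only {int(ok.sum())} sites survive conditioning "
            f"(need >= {min_sites}); filter ledger: {ledger}"
        )
    return ContinuityInput(y[ok], der_row[ok], tot_row[ok], ledger)


def _genotype_probs(x: np.ndarray, t2: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(g | x, t2) for g in {0, 1, 2}; closed form via the first two
    moments of the drifted frequency z ~ BN(mean x, var t2 x(1-x))."""
    v = t2 * x * (1.0 - x)
    p2 = x * x + v
    p0 = (1.0 - x) ** 2 + v
    p1 = 2.0 * x * (1.0 - x) * (1.0 - t2)
    return p0, p1, p2


def _read_loglik_terms(derived, total, error_rate):
    """log Binomial(d | n, r_g) for each genotype g, up to the common
    binomial coefficient (which cancels in likelihood ratios but is kept
    for absolute values)."""
    from scipy.special import gammaln

    d = derived.astype(float)
    n = total.astype(float)
    logcoef = gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1)

    def term(r):
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = d * np.log(r) + (n - d) * np.log1p(-r)
        lp = np.where((d == 0) & (r == 0.0), 0.0, lp)
        lp = np.where((d == n) & (r == 1.0), 0.0, lp)
        return logcoef + lp

    e = error_rate
    return term(np.full_like(d, e)), term(np.full_like(d, 0.5)), term(np.full_like(d, 1.0 - e))


def continuity_loglik(
    inp: ContinuityInput,
    t1: float,
    t2: float,
    error_rate: float = 0.0,
    n_nodes: int = 64,
) -> float:
    """Log-likelihood of the read counts under drift parameters (t1, t2).

    ``t1`` is the drift between the ancestral population and the target;
    ``t2`` the drift private to the specimen's branch (0 = direct
    ancestry).  Integration over the ancestral frequency uses ``n_nodes``
    Gauss-Legendre nodes carrying the reversed-time ancestor weight
    ``BN(y | x, t1)`` (uniform ancestral prior), renormalized on the
    quadrature grid; ``t1 -> 0`` collapses to ``x = y`` exactly.  Returns
    ``-inf`` when the likelihood underflows at extreme parameters.
    """
    from scipy.special import gammaln

    if t1 < 0 or t2 < 0:
        raise ValueError("drift parameters must be >= 0")
    y = inp.y
    l0, l1, l2 = _read_loglik_terms(inp.derived, inp.total, error_rate)
    lik_terms = np.exp(np.stack([l0, l1, l2]))  # 3 x S

    if t1 <= _T_MIN:
        p0, p1, p2 = _genotype_probs(y, t2)
        site_lik = p0 * lik_terms[0] + p1 * lik_terms[1] + p2 * lik_terms[2]
    else:
        nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
        x = 0.5 * (nodes + 1.0)  # map to (0, 1)
        w = 0.5 * weights
        scale = (1.0 - t1) / t1
        a = x * scale  # per-node Beta parameters of the forward y | x kernel
        b = (1.0 - x) * scale
        # f(x | y) on the grid: Beta density of y with x-dependent shape,
        # including the x-dependent normalizer, renormalized to unit mass
        logf = (
            (a[None, :] - 1.0) * np.log(y[:, None])
            + (b[None, :] - 1.0) * np.log1p(-y[:, None])
            + gammaln(scale)
            - gammaln(a[None, :])
            - gammaln(b[None, :])
        )
        logf -= logf.max(axis=1, keepdims=True)
        f = np.exp(logf) * w[None, :]
        f /= f.sum(axis=1, keepdims=True)  # S x nodes
        p0, p1, p2 = _genotype_probs(x[None, :], t2)
        mix = (
            f * p0 * lik_terms[0][:, None]
            + f * p1 * lik_terms[1][:, None]
            + f * p2 * lik_terms[2][:, None]
        )
        site_lik = mix.sum(axis=1)
    if np.any(site_lik <= 0.0) or not np.all(np.isfinite(site_lik)):
        return -np.inf
    return float(np.log(site_lik).sum())


def _maximize(inp, free_t2: bool, error_rate: float, n_nodes: int):
    """Bounded maximization of the log-likelihood from multiple starts."""

    if free_t2:
        def nll(theta):
            ll = continuity_loglik(inp, theta[0], theta[1], error_rate, n_nodes)
            return -ll if np.isfinite(ll) else 1e12

        starts = [(0.01, 0.01), (0.05, 0.001), (0.001, 0.05), (0.1, 0.1)]
        bounds = [(0.0, _T_MAX), (0.0, _T_MAX)]
    else:
        def nll(theta):
            ll = continuity_loglik(inp, theta[0], 0.0, error_rate, n_nodes)
            return -ll if np.isfinite(ll) else 1e12

        starts = [(0.001,), (0.01,), (0.05,), (0.2,)]
        bounds = [(0.0, _T_MAX)]

    best = None
    for s in starts:
        res = optimize.minimize(
            nll, np.asarray(s), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("continuity optimizer failed to converge")
    return -best.fun, best.x


def continuity_lrt(
    inp: ContinuityInput, error_rate: float = 0.0, n_nodes: int = 64
) -> ContinuityResult:
    """Likelihood-ratio test of direct ancestry versus sister-group placement.

    Maximizes the likelihood over ``(t1, t2)`` (full model) and over
    ``t1`` with ``t2 = 0`` (direct ancestry); the statistic
    ``2 (LL_full - LL_null)`` is referred to ``1/2 chi2_0 + 1/2 chi2_1``.
    Small p-values reject direct ancestry.
    """
    ll_null, x_null = _maximize(inp, free_t2=False, error_rate=error_rate, n_nodes=n_nodes)
    ll_full, x_full = _maximize(inp, free_t2=True, error_rate=error_rate, n_nodes=n_nodes)
    if ll_full < ll_null:  # nested models: refine full from the null optimum
        ll_ref, x_ref = ll_null, np.array([x_null[0], 0.0])
        if ll_ref > ll_full:
            ll_full, x_full = ll_ref, x_ref
    lrt = 2.0 * (ll_full - ll_null)
    if lrt < -1e-6:
        raise RuntimeError(f"negative LRT {lrt}; optimizer failure")
    lrt = max(lrt, 0.0)
    p = 1.0 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return ContinuityResult(
        t1_hat=float(x_full[0]),
        t2_hat=float(x_full[1]),
        ll_full=ll_full,
        ll_null=ll_null,
        lrt=lrt,
        p_value=p,
        n_sites=inp.n_sites,
        provenance=dict(inp.provenance),
    )


def simulate_continuity_data(
    n_sites: int,
    t1: float,
    t2: float,
    seed: int,
    mean_depth: float = 2.0,
    error_rate: float = 0.0,
) -> ContinuityInput:
    """Generate read counts from the test's own generative model.

    Ancestral frequencies ``x`` are uniform on (0, 1) (the model's
    ancestral prior); the target frequency ``y`` descends by a forward
    Balding-Nichols step of magnitude ``t1`` and is treated as exact; the
    specimen's population frequency ``z`` drifts from ``x`` by ``t2``;
    genotypes are Binomial(2, z) and reads Binomial(total, g/2) with
    ``total ~ 1 + Poisson(mean_depth - 1)``.  Sites are kept while ``y``
    stays inside (0.02, 0.98), mimicking conditioning on segregating
    variants.
    """
    rng = np.random.default_rng(seed)
    x_all = rng.uniform(0.0, 1.0, size=n_sites * 4)
    if t1 <= _T_MIN:
        y_all = x_all
    else:
        scale = (1.0 - t1) / t1
        with np.errstate(invalid="ignore"):
            y_all = rng.beta(
                np.maximum(x_all, 1e-12) * scale, np.maximum(1.0 - x_all, 1e-12) * scale
            )
    ok = (y_all > 0.02) & (y_all < 0.98)
    x = x_all[ok][:n_sites]
    y = y_all[ok][:n_sites]
    if len(y) < n_sites:
        raise ValueError("not enough segregating sites; increase n_sites")
    if t2 <= _T_MIN:
        z = x
    else:
        scale2 = (1.0 - t2) / t2
        z = np.where(
            (x > 0) & (x < 1),
            rng.beta(np.maximum(x, 1e-12) * scale2, np.maximum(1.0 - x, 1e-12) * scale2),
            x,
        )
    n = len(y)
    total = 1 + rng.poisson(max(mean_depth - 1.0, 0.05), size=n)
    g = rng.binomial(2, np.clip(z, 0, 1))
    pr = (g / 2.0) * (1.0 - error_rate) + (1.0 - g / 2.0) * error_rate
    derived = rng.binomial(total, pr)
    return ContinuityInput(y, derived, total, {"simulated": True, "t1": t1, "t2": t2})
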