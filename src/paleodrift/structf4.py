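"""Ancestry decomposition from f4-style coancestries by adaptive MCMC.

The model: each individual ``i`` carries a mixing vector ``q_i`` on the
K-simplex over K ancestral populations whose pairwise shared drift
(relative to an outgroup) is a symmetric PSD matrix ``Omega``.  Because
individual allele frequencies are linear mixtures of ancestral
frequencies, the expected outgroup coancestry of two individuals is

    c_ij = q_i' Omega q_j            (i != j),

and every f4-statistic among panel members and the outgroup is a linear
combination of such coancestries.  Observed coancestries are modelled as
independent Gaussians around their expectation, with per-statistic
standard errors when supplied and a shared residual scale ``sigma``
estimated jointly otherwise.

Inference runs a component-wise random-walk Metropolis-Hastings sampler on
transformed parameters (Q rows via additive log-ratio, Omega via a
Cholesky factor with log diagonal, sigma via log), with transform
Jacobians included so the target is the posterior under flat priors on
Omega and sigma and a symmetric Dirichlet(alpha) prior on each mixing
row.  The Dirichlet concentration matters: the quadratic-form model is
invariant under ``Q -> Q A``, ``Omega -> A^-1 Omega A^-T`` for any
invertible stochastic matrix ``A``, so the likelihood alone identifies the
decomposition only up to this gauge.  A sparsity-favoring ``alpha < 1``
(default 0.25) anchors the gauge at the vertex-spanning solution — the
one in which unadmixed individuals sit at simplex corners — which is the
true decomposition whenever the panel contains unadmixed representatives
of each ancestry.  Proposal scales adapt toward a target acceptance rate
during burn-in and are frozen afterwards; the reported fit is the
maximum-likelihood state visited, with the post-burn-in posterior mean
exported alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import CoancestryMatrix

__all__ = [
    "AncestryParams",
    "McmcSettings",
    "StructF4Fit",
    "expected_coancestry",
    "expected_f4",
    "loglik",
    "fit_structf4",
    "align_components",
    "mds",
]


@dataclass
class AncestryParams:
    """K-component ancestry model: mixing matrix Q, drift matrix Omega, scale sigma."""

    Q: np.ndarray  # N x K, rows on the simplex
    omega: np.ndarray  # K x K symmetric PSD
    sigma: float = 1.0

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.Q.ndim != 2:
            raise ValueError("Q must be N x K")
        K = self.Q.shape[1]
        if self.omega.shape != (K, K):
            raise ValueError("omega must be K x K")
        if np.any(self.Q < -1e-12) or np.any(np.abs(self.Q.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("Q rows must be non-negative and sum to 1")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh((self.omega + self.omega.T) / 2)) < -1e-8:
            raise ValueError("omega must be positive semi-definite")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclass
class McmcSettings:
    iterations: int = 4000  # sweeps; each sweep updates every parameter block once
    burnin: int = 2000
    thinning: int = 10
    target_accept: float = 0.234
    seed: int = 0
    n_restarts: int = 5
    adapt_power: float = 0.6
    dirichlet_alpha: float = 0.25  # prior concentration on Q rows; see note below

    def __post_init__(self):
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("need 0 <= burnin < iterations")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target acceptance must be in (0, 1)")
        if not (self.dirichlet_alpha > 0.0):
            raise ValueError("dirichlet_alpha must be > 0")


def expected_coancestry(params: AncestryParams) -> np.ndarray:
    """c_ij = q_i' Omega q_j; only off-diagonal entries are model-meaningful."""
    return params.Q @ params.omega @ params.Q.T


def expected_f4(
    params: AncestryParams,
    quadruples: list[tuple[str, str, str, str]],
    labels: list[str],
    outgroup_label: str = "O",
) -> np.ndarray:
    """Model-expected f4 for each (i, j; k, l) quadruple of labels.

    f4(i,j;k,l) = c_ik - c_il - c_jk + c_jl, where the outgroup label has
    zero coancestry with everything.
    """
    chat = expected_coancestry(params)
    n = params.n
    index = {lab: i for i, lab in enumerate(labels)}

    def c(a: str, b: str) -> float:
        if a == outgroup_label or b == outgroup_label:
            return 0.0
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            raise KeyError(f"unknown label {a if ia is None else b!r}")
        return chat[ia, ib]

    out = np.empty(len(quadruples))
    for m, (i, j, k, l) in enumerate(quadruples):
        out[m] = c(i, k) - c(i, l) - c(j, k) + c(j, l)
    return out


def _offdiag_residuals(params: AncestryParams, obs: np.ndarray) -> np.ndarray:
    chat = expected_coancestry(params)
    iu, ju = np.triu_indices(params.n, k=1)
    return obs[iu, ju] - chat[iu, ju]


def loglik(
    params: AncestryParams, obs: np.ndarray, se: np.ndarray | None = None
) -> float:
    """Gaussian log-likelihood of the observed coancestry off-diagonals.

    With ``se`` (per-statistic standard errors, N x N), each statistic gets
    its own scale; otherwise the shared ``params.sigma`` applies.
    """
    obs = np.asarray(obs, dtype=float)
    if not np.all(np.isfinite(obs[np.triu_indices(params.n, k=1)])):
        raise ValueError("non-finite observed statistics")
    r = _offdiag_residuals(params, obs)
    if se is not None:
        iu, ju = np.triu_indices(params.n, k=1)
        s = np.asarray(se, dtype=float)[iu, ju]
    else:
        s = np.full(r.shape, params.sigma)
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * s**2) - r**2 / (2.0 * s**2)))


# ---------------------------------------------------------------------------
# sampler internals


def _q_from_z(z: np.ndarray) -> np.ndarray:
    """Inverse additive log-ratio: rows of z (K-1) -> simplex rows (K)."""
    z = np.atleast_2d(z)
    full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _chol_from_state(lam: np.ndarray, off: np.ndarray, K: int) -> np.ndarray:
    L = np.zeros((K, K))
    L[np.diag_indices(K)] = np.exp(lam)
    if K > 1:
        L[np.tril_indices(K, k=-1)] = off
    return L


def _vertex_decompose(obs: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertex-anchored decomposition (Q, Omega, resid_sd) of a coancestry matrix.

    Because coancestry rows are affine images of the mixing vectors, the
    panel lies on a (K-1)-dimensional affine subspace on which the mixing
    simplex maps to a geometric simplex whose vertices are the images of
    the pure ancestries.  Project the (diagonal-repaired) matrix to its
    top K-1 principal axes, pick K vertices by the furthest-point rule
    refined by averaging each vertex's nearest individuals, and read each
    individual's mixing vector off as simplex-constrained barycentric
    coordinates; Omega then solves the off-diagonal model equations by
    least squares.  This both initializes the sampler and fixes the
    stochastic-matrix gauge of a fitted state.
    """
    from scipy.optimize import nnls

    N = obs.shape[0]
    C = obs.copy()
    off = C.copy()
    np.fill_diagonal(off, -np.inf)
    np.fill_diagonal(C, off.max(axis=1))
    X = C - C.mean(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    P = X @ Vt[: max(K - 1, 1)].T  # N x (K-1) coordinates

    anchors = [int(np.argmax(np.linalg.norm(P, axis=1)))]
    while len(anchors) < K:
        d = np.min(
            [np.linalg.norm(P - P[a], axis=1) for a in anchors], axis=0
        )
        anchors.append(int(np.argmax(d)))
    V = P[anchors]  # K x (K-1)

    def _barycentric(V):
        tau = 10.0 * (np.abs(V).max() + 1e-12)
        A_mat = np.vstack([V.T, tau * np.ones(K)])  # (K-1+1) x K
        Q0 = np.empty((N, K))
        for i in range(N):
            b = np.concatenate([P[i], [tau]])
            q, _ = nnls(A_mat, b)
            s = q.sum()
            Q0[i] = q / s if s > 0 else np.full(K, 1.0 / K)
        return Q0

    # denoise the vertices: average the individuals assigned to each
    # vertex's cluster (membership threshold, which avoids the outward
    # selection bias of picking the most extreme points)
    Q0 = _barycentric(V)
    for _ in range(3):
        for a in range(K):
            sel = np.flatnonzero(Q0[:, a] > 0.8)
            if len(sel) < 3:
                sel = np.argsort(-Q0[:, a])[: max(5, N // 20)]
            V[a] = P[sel].mean(axis=0)
        Q0 = _barycentric(V)
    Q0 = np.clip(Q0, 1e-4, None)
    Q0 /= Q0.sum(axis=1, keepdims=True)

    iu, ju = np.triu_indices(N, k=1)
    pairs = [(a, b) for a in range(K) for b in range(a, K)]
    design = np.empty((len(iu), len(pairs)))
    for m, (a, b) in enumerate(pairs):
        if a == b:
            design[:, m] = Q0[iu, a] * Q0[ju, a]
        else:
            design[:, m] = Q0[iu, a] * Q0[ju, b] + Q0[iu, b] * Q0[ju, a]
    sol, *_ = np.linalg.lstsq(design, obs[iu, ju], rcond=None)
    Om0 = np.zeros((K, K))
    for m, (a, b) in enumerate(pairs):
        Om0[a, b] = Om0[b, a] = sol[m]
    w_eig, v_eig = np.linalg.eigh(Om0)
    Om0 = (v_eig * np.clip(w_eig, 1e-6, None)) @ v_eig.T
    resid = obs[iu, ju] - design @ sol
    sigma0 = float(max(np.std(resid), 1e-6))
    return Q0, Om0, sigma0


class _Chain:
    """One adaptive MH chain on the transformed parameter space."""

    def __init__(self, obs, K, settings, se, rng, init=None, init_scale=0.2):
        self.obs = np.asarray(obs, dtype=float)
        self.N = self.obs.shape[0]
        self.K = K
        self.settings = settings
        self.rng = rng
        iu, ju = np.triu_indices(self.N, k=1)
        self.iu, self.ju = iu, ju
        self.M = len(iu)
        if se is not None:
            self.w = 1.0 / np.asarray(se, dtype=float) ** 2  # N x N weights
            self.const = float(
                np.sum(-0.5 * np.log(2.0 * np.pi / self.w[iu, ju]))
            )
        else:
            self.w = None
            self.const = None

        mean_c = float(np.mean(self.obs[iu, ju]))
        base = max(abs(mean_c), 1e-3)
        if init is not None:
            q0, om0, sig0 = init
            q0 = np.clip(q0, 1e-6, None)
            q0 /= q0.sum(axis=1, keepdims=True)
            L0 = np.linalg.cholesky(om0 + 1e-9 * np.eye(K))
            self.lam = np.log(np.diag(L0))
            self.off = L0[np.tril_indices(K, k=-1)]
            self.Z = (
                np.log(q0[:, :-1]) - np.log(q0[:, -1:]) if K > 1 else np.zeros((self.N, 0))
            )
            self.logsig = math.log(sig0) if self.w is None else 0.0
        else:
            # fallback: Q ~ Dirichlet(1), Omega = mean coancestry * identity
            self.lam = np.full(K, 0.5 * np.log(base))
            self.off = np.zeros(K * (K - 1) // 2)
            if K > 1:
                q0 = rng.dirichlet(np.ones(K), size=self.N)
                q0 = np.clip(q0, 1e-6, None)
                q0 /= q0.sum(axis=1, keepdims=True)
                self.Z = np.log(q0[:, :-1]) - np.log(q0[:, -1:])
            else:
                self.Z = np.zeros((self.N, 0))
            self.logsig = math.log(init_scale * base) if self.w is None else 0.0

        self._sync()
        # proposal scales per block: N row blocks, K(K+1)/2 omega blocks, sigma
        self.n_omega = K * (K + 1) // 2
        self.s_row = np.full(self.N, 0.5)
        self.s_omega = np.full(self.n_omega, 0.2)
        self.s_sig = 0.3
        self.acc_row = np.zeros(self.N)
        self.acc_omega = np.zeros(self.n_omega)
        self.acc_sig = 0.0
        self.post_count = 0

    # -- state-dependent caches ------------------------------------------
    def _sync(self):
        self.Q = _q_from_z(self.Z) if self.K > 1 else np.ones((self.N, 1))
        L = _chol_from_state(self.lam, self.off, self.K)
        self.omega = L @ L.T
        self.QOm = self.Q @ self.omega
        self.chat = self.QOm @ self.Q.T
        self.sigma = math.exp(self.logsig)

    def _ssr(self) -> float:
        r = self.obs[self.iu, self.ju] - self.chat[self.iu, self.ju]
        if self.w is None:
            return float(np.sum(r * r))
        return float(np.sum(self.w[self.iu, self.ju] * r * r))

    def loglik_of_ssr(self, ssr: float) -> float:
        if self.w is None:
            s2 = self.sigma**2
            return -0.5 * self.M * math.log(2.0 * math.pi * s2) - ssr / (2.0 * s2)
        return self.const - 0.5 * ssr

    # -- block updates ---------------------------------------------------
    def _row_delta(self, i, q_new):
        """Change in weighted SSR from replacing row i of Q."""
        new_row = self.QOm @ q_new  # c_ij for all j (j = i unused)
        old_row = self.chat[i]
        r_new = self.obs[i] - new_row
        r_old = self.obs[i] - old_row
        if self.w is None:
            d = r_new * r_new - r_old * r_old
        else:
            d = self.w[i] * (r_new * r_new - r_old * r_old)
        d[i] = 0.0
        return float(d.sum()), new_row

    def _update_rows(self, ssr, adapt, gamma):
        inv2s2 = 1.0 / (2.0 * self.sigma**2) if self.w is None else 0.5
        for i in range(self.N):
            z_new = self.Z[i] + self.s_row[i] * self.rng.standard_normal(self.K - 1)
            q_new = _q_from_z(z_new[None, :])[0]
            dssr, new_row = self._row_delta(i, q_new)
            # Dirichlet(alpha) prior density q^(alpha-1) times the ALR
            # Jacobian q^1 gives exponent alpha on each component
            qi = np.clip(self.Q[i], 1e-300, None)
            qn = np.clip(q_new, 1e-300, None)
            alpha = self.settings.dirichlet_alpha
            djac = alpha * float(np.sum(np.log(qn)) - np.sum(np.log(qi)))
            log_alpha = -dssr * inv2s2 + djac
            accept = math.log(self.rng.random() + 1e-300) < log_alpha
            if accept:
                self.Z[i] = z_new
                self.Q[i] = q_new
                self.QOm[i] = q_new @ self.omega
                self.chat[i, :] = new_row
                self.chat[:, i] = new_row
                self.chat[i, i] = float(q_new @ self.omega @ q_new)
                ssr += dssr
            if adapt:
                self.s_row[i] *= math.exp(
                    gamma * ((1.0 if accept else 0.0) - self.settings.target_accept)
                )
            else:
                self.acc_row[i] += 1.0 if accept else 0.0
        return ssr

    def _omega_state(self):
        return np.concatenate([self.lam, self.off])

    def _set_omega_state(self, theta):
        self.lam = theta[: self.K].copy()
        self.off = theta[self.K :].copy()
        L = _chol_from_state(self.lam, self.off, self.K)
        self.omega = L @ L.T
        self.QOm = self.Q @ self.omega
        self.chat = self.QOm @ self.Q.T

    def _update_omega(self, ssr, adapt, gamma):
        inv2s2 = 1.0 / (2.0 * self.sigma**2) if self.w is None else 0.5
        for b in range(self.n_omega):
            theta = self._omega_state()
            theta_new = theta.copy()
            theta_new[b] += self.s_omega[b] * self.rng.standard_normal()
            old = (self.lam.copy(), self.off.copy(), self.omega, self.QOm, self.chat)
            old_jac = float(np.sum((self.K - np.arange(self.K) + 1) * self.lam))
            self._set_omega_state(theta_new)
            new_jac = float(np.sum((self.K - np.arange(self.K) + 1) * self.lam))
            ssr_new = self._ssr()
            log_alpha = -(ssr_new - ssr) * inv2s2 + (new_jac - old_jac)
            accept = math.log(self.rng.random() + 1e-300) < log_alpha
            if accept:
                ssr = ssr_new
            else:
                self.lam, self.off, self.omega, self.QOm, self.chat = old
            if adapt:
                self.s_omega[b] *= math.exp(
                    gamma * ((1.0 if accept else 0.0) - self.settings.target_accept)
                )
            else:
                self.acc_omega[b] += 1.0 if accept else 0.0
        return ssr

    def _update_sigma(self, ssr, adapt, gamma):
        if self.w is not None:
            return
        logsig_new = self.logsig + self.s_sig * self.rng.standard_normal()
        # log target in sigma: -M log(sigma) - ssr/(2 sigma^2) + log(sigma) [Jacobian]
        def lt(ls):
            s2 = math.exp(2.0 * ls)
            return -(self.M - 1) * ls - ssr / (2.0 * s2)

        log_alpha = lt(logsig_new) - lt(self.logsig)
        accept = math.log(self.rng.random() + 1e-300) < log_alpha
        if accept:
            self.logsig = logsig_new
            self.sigma = math.exp(self.logsig)
        if adapt:
            self.s_sig *= math.exp(
                gamma * ((1.0 if accept else 0.0) - self.settings.target_accept)
            )
        else:
            self.acc_sig += 1.0 if accept else 0.0

    # -- main loop -------------------------------------------------------
    def run(self):
        st = self.settings
        ssr = self._ssr()
        trace = np.empty(st.iterations)
        best_ll = -np.inf
        best = None
        mean_Q = np.zeros_like(self.Q)
        mean_omega = np.zeros_like(self.omega)
        mean_sigma = 0.0
        omega_draws: list[np.ndarray] = []
        sigma_draws: list[float] = []
        n_kept = 0
        n_post = 0
        for t in range(st.iterations):
            adapt = t < st.burnin
            gamma = 1.0 / (1.0 + t) ** st.adapt_power if adapt else 0.0
            if self.K > 1:
                ssr = self._update_rows(ssr, adapt, gamma)
            ssr = self._update_omega(ssr, adapt, gamma)
            self._update_sigma(ssr, adapt, gamma)
            if t % 200 == 199:
                ssr = self._ssr()  # resync against float drift
            ll = self.loglik_of_ssr(ssr)
            trace[t] = ll
            if ll > best_ll:
                best_ll = ll
                best = (self.Q.copy(), self.omega.copy(), self.sigma)
            if not adapt:
                n_post += 1
                if (t - st.burnin) % st.thinning == 0:
                    mean_Q += self.Q
                    mean_omega += self.omega
                    mean_sigma += self.sigma
                    omega_draws.append(self.omega.copy())
                    sigma_draws.append(self.sigma)
                    n_kept += 1
        self.post_count = n_post
        post_mean = None
        if n_kept:
            post_mean = (mean_Q / n_kept, mean_omega / n_kept, mean_sigma / n_kept)
        acc = {
            "rows": self.acc_row / max(n_post, 1),
            "omega": self.acc_omega / max(n_post, 1),
            "sigma": self.acc_sig / max(n_post, 1),
        }
        draws = (np.array(omega_draws), np.array(sigma_draws))
        return best_ll, best, trace, post_mean, acc, draws


@dataclass
class StructF4Fit:
    """Result of an ancestry-decomposition run."""

    params: AncestryParams  # best-likelihood state, components sorted
    loglik: float
    trace: np.ndarray  # per-sweep log-likelihood of the winning chain
    acceptance: dict  # post-burn-in acceptance rates per block family
    fitted: np.ndarray  # expected coancestry at the best state
    residual: np.ndarray  # observed - fitted (off-diagonal meaningful)
    posterior_mean: AncestryParams | None
    labels: list[str] = field(default_factory=list)
    restart_logliks: list[float] = field(default_factory=list)
    omega_draws: np.ndarray | None = None  # thinned post-burn-in draws
    sigma_draws: np.ndarray | None = None

    def q_frame(self) -> pd.DataFrame:
        cols = [f"K{k + 1}" for k in range(self.params.K)]
        return pd.DataFrame(self.params.Q, index=self.labels or None, columns=cols)


def _sorted_components(Q, omega):
    order = np.argsort(-Q.sum(axis=0), kind="stable")
    return Q[:, order], omega[np.ix_(order, order)]


def fit_structf4(
    obs,
    K: int,
    settings: McmcSettings | None = None,
    se: np.ndarray | None = None,
) -> StructF4Fit:
    """Decompose an observed coancestry matrix into K ancestry components.

    ``obs`` is a :class:`~paleodrift.stats.CoancestryMatrix` or a plain
    symmetric array (only off-diagonals are used).  Runs
    ``settings.n_restarts`` independent adaptive MH chains and returns the
    best-likelihood state visited, with components sorted by total
    contribution.  Deterministic given ``settings.seed``.
    """
    settings = settings or McmcSettings()
    if isinstance(obs, CoancestryMatrix):
        labels = obs.labels
        obs_mat = obs.values
    else:
        obs_mat = np.asarray(obs, dtype=float)
        labels = [str(i) for i in range(obs_mat.shape[0])]
    N = obs_mat.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if N < K:
        raise ValueError("need at least K individuals")

    root = np.random.default_rng(settings.seed)
    init = _vertex_decompose(obs_mat, K) if K > 1 else None
    best = None
    restart_lls = []
    for r in range(settings.n_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        if init is not None:
            q0, om0, sig0 = init
            if r > 0:  # jitter later restarts around the anchored start
                jit = 0.15 * r
                q0 = np.clip(q0 + jit * rng.dirichlet(np.ones(K), size=q0.shape[0]) - jit / K, 1e-4, None)
                q0 = q0 / q0.sum(axis=1, keepdims=True)
                om0 = om0 * np.exp(jit * rng.standard_normal())
            chain = _Chain(obs_mat, K, settings, se, rng, init=(q0, om0, sig0))
        else:
            chain = _Chain(obs_mat, K, settings, se, rng)
        out = chain.run()
        restart_lls.append(out[0])
        if best is None or out[0] > best[0]:
            best = out
    best_ll, (Q, omega, sigma), trace, post_mean, acc, draws = best
    if K > 1:
        # The likelihood identifies only the fitted coancestry Q Omega Q';
        # re-anchor the reported decomposition on the (denoised) fitted
        # matrix so the gauge convention is vertex-spanning.
        chat_best = Q @ omega @ Q.T
        Q, omega, _ = _vertex_decompose(chat_best, K)
    Qs, omegas = _sorted_components(Q, omega)
    params = AncestryParams(Qs, omegas, sigma)
    fitted = expected_coancestry(params)
    best_ll = loglik(params, obs_mat, se)
    pm = None
    if post_mean is not None:
        pq = np.clip(post_mean[0], 1e-6, None)
        pq /= pq.sum(axis=1, keepdims=True)
        pO = (post_mean[1] + post_mean[1].T) / 2
        w_eig, v_eig = np.linalg.eigh(pO)
        pO = (v_eig * np.clip(w_eig, 1e-9, None)) @ v_eig.T
        if K > 1:  # same gauge convention as the reported state
            pq, pO, _ = _vertex_decompose(pq @ pO @ pq.T, K)
        pQ, pO = _sorted_components(pq, pO)
        pm = AncestryParams(pQ, pO, max(post_mean[2], 1e-12))
    return StructF4Fit(
        params=params,
        loglik=best_ll,
        trace=trace,
        acceptance=acc,
        fitted=fitted,
        residual=obs_mat - fitted,
        posterior_mean=pm,
        labels=labels,
        restart_logliks=restart_lls,
        omega_draws=draws[0],
        sigma_draws=draws[1],
    )


def align_components(
    Q_est: np.ndarray, Q_ref: np.ndarray
) -> tuple[tuple[int, ...], np.ndarray]:
    """Resolve label switching: the column permutation of ``Q_est``
    minimizing total L1 error against ``Q_ref`` (exhaustive for K <= 8,
    greedy beyond)."""
    Q_est = np.asarray(Q_est, dtype=float)
    Q_ref = np.asarray(Q_ref, dtype=float)
    if Q_est.shape != Q_ref.shape:
        raise ValueError("shapes must match")
    K = Q_est.shape[1]
    cost = np.array(
        [[np.abs(Q_est[:, a] - Q_ref[:, b]).sum() for b in range(K)] for a in range(K)]
    )
    if K <= 8:
        best_perm, best_cost = None, np.inf
        for perm in itertools.permutations(range(K)):
            c = sum(cost[perm[b], b] for b in range(K))
            if c < best_cost:
                best_cost, best_perm = c, perm
    else:  # greedy fallback
        remaining = set(range(K))
        best_perm = [0] * K
        for b in range(K):
            a = min(remaining, key=lambda a_: cost[a_, b])
            best_perm[b] = a
            remaining.discard(a)
        best_perm = tuple(best_perm)
    return best_perm, Q_est[:, list(best_perm)]


def mds(
    coan: CoancestryMatrix, exclude_labels: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical multidimensional scaling of the coancestry semi-matrix.

    Similarities convert to dissimilarities ``d_ij = c_max - c_ij`` with
    ``c_max`` the largest off-diagonal coancestry and a zero diagonal;
    double-centering and eigendecomposition give coordinates for the
    positive eigenvalues, in non-increasing eigenvalue order.
    """
    exclude = set(exclude_labels or [])
    keep = [l for l in coan.labels if l not in exclude]
    idx = [coan.labels.index(l) for l in keep]
    C = coan.values[np.ix_(idx, idx)]
    n = len(keep)
    offmask = ~np.eye(n, dtype=bool)
    cmax = float(C[offmask].max())
    D = cmax - C
    np.fill_diagonal(D, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    w, v = np.linalg.eigh(B)
    order = np.argsort(-w)
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    if not pos.any():
        coords = pd.DataFrame(np.zeros((n, 1)), index=keep, columns=["MDS1"])
        return coords, w
    coords = v[:, pos] * np.sqrt(w[pos])
    cols = [f"MDS{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=keep, columns=cols), w
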