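"""Ancestry mixture model: expectations, likelihood, sampler, alignment, MDS."""

import itertools

import numpy as np
import pytest

from paleodrift.stats import CoancestryMatrix, coancestry
from paleodrift.structf4 import (
    AncestryParams,
    McmcSettings,
    align_components,
    expected_coancestry,
    expected_f4,
    fit_structf4,
    loglik,
    mds,
)


def params_fixture():
    Q = np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0], [0.3, 0.7]])
    omega = np.array([[2.0, 1.0], [1.0, 3.0]])
    return AncestryParams(Q, omega, sigma=0.5)


class TestExpectations:
    def test_k1_constant_coancestry(self):
        p = AncestryParams(np.ones((4, 1)), np.array([[0.7]]), 1.0)
        chat = expected_coancestry(p)
        assert np.allclose(chat, 0.7)

    def test_one_hot_pairs_read_omega(self):
        p = params_fixture()
        chat = expected_coancestry(p)
        assert chat[1, 2] == pytest.approx(1.0)  # omega_ab

    def test_mixed_pair_example(self):
        p = params_fixture()
        chat = expected_coancestry(p)
        # q_i=(0.5,0.5), q_j=(1,0): 0.5*2 + 0.5*1 = 1.5
        assert chat[0, 1] == pytest.approx(1.5)

    def test_f4_from_coancestry_identities(self):
        p = params_fixture()
        labels = ["a", "b", "c", "d"]
        assert expected_f4(p, [("a", "a", "c", "d")], labels)[0] == 0.0
        chat = expected_coancestry(p)
        val = expected_f4(p, [("a", "O", "b", "O")], labels)[0]
        assert val == pytest.approx(chat[0, 1])

    def test_f4_additivity_exact(self):
        p = params_fixture()
        labels = ["a", "b", "c", "d"]
        whole = expected_f4(p, [("a", "b", "c", "d")], labels)[0]
        parts = expected_f4(p, [("a", "d", "c", "d"), ("d", "b", "c", "d")], labels)
        assert whole == pytest.approx(parts.sum(), abs=1e-14)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            expected_f4(params_fixture(), [("a", "z", "c", "d")], ["a", "b", "c", "d"])


class TestLoglik:
    def test_zero_residual_closed_form(self):
        p = params_fixture()
        obs = expected_coancestry(p)
        M = 4 * 3 // 2
        se = np.ones((4, 4))
        assert loglik(p, obs, se) == pytest.approx(-0.5 * M * np.log(2 * np.pi))

    def test_doubling_sigma_costs_m_log_two(self):
        p = params_fixture()
        obs = expected_coancestry(p)
        M = 6
        p2 = AncestryParams(p.Q, p.omega, sigma=2 * p.sigma)
        assert loglik(p, obs) - loglik(p2, obs) == pytest.approx(M * np.log(2.0))

    def test_one_se_perturbation_costs_half(self):
        p = params_fixture()
        obs = expected_coancestry(p).copy()
        se = np.full((4, 4), 0.3)
        base = loglik(p, obs, se)
        obs[0, 1] += 0.3
        obs[1, 0] += 0.3
        assert base - loglik(p, obs, se) == pytest.approx(0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AncestryParams(np.array([[0.5, 0.4]]), np.eye(2), 1.0)
        with pytest.raises(ValueError, match="semi-definite"):
            AncestryParams(np.array([[0.5, 0.5]]), np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)


class TestAlignComponents:
    def test_recovers_column_shuffle(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(4), size=30)
        perm = (2, 0, 3, 1)
        shuffled = Q[:, list(perm)]
        found, aligned = align_components(shuffled, Q)
        assert np.allclose(aligned, Q)

    def test_identity_for_identical(self):
        Q = np.random.default_rng(1).dirichlet(np.ones(3), size=10)
        perm, aligned = align_components(Q, Q)
        assert perm == (0, 1, 2)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        A = rng.dirichlet(np.ones(4), size=15)
        B = rng.dirichlet(np.ones(4), size=15)
        perm, aligned = align_components(A, B)
        best = min(
            itertools.permutations(range(4)),
            key=lambda p: np.abs(A[:, list(p)] - B).sum(),
        )
        assert np.abs(aligned - B).sum() == pytest.approx(
            np.abs(A[:, list(best)] - B).sum()
        )


class TestSampler:
    def test_k1_rows_forced_to_one(self):
        rng = np.random.default_rng(3)
        obs = np.full((6, 6), 0.05) + rng.normal(0, 0.005, (6, 6))
        obs = (obs + obs.T) / 2
        fit = fit_structf4(obs, K=1, settings=McmcSettings(iterations=400, burnin=200, seed=1, n_restarts=1))
        assert np.all(fit.params.Q == 1.0)

    def test_conjugate_toy_posterior_mean(self):
        # K=1: observations N(omega11, sigma); flat priors -> posterior of
        # omega11 centered at the sample mean
        rng = np.random.default_rng(4)
        N = 15
        iu, ju = np.triu_indices(N, 1)
        vals = rng.normal(0.05, 0.004, size=len(iu))
        obs = np.zeros((N, N))
        obs[iu, ju] = vals
        obs[ju, iu] = vals
        fit = fit_structf4(
            obs, K=1,
            settings=McmcSettings(iterations=6000, burnin=2000, thinning=5, seed=9, n_restarts=1),
        )
        draws = fit.omega_draws[:, 0, 0]
        # Monte-Carlo SE by batch means
        n_batch = 20
        batches = np.array_split(draws, n_batch)
        bm = np.array([b.mean() for b in batches])
        mc_se = bm.std(ddof=1) / np.sqrt(n_batch)
        assert abs(draws.mean() - vals.mean()) < 3 * mc_se + 1e-12
        for fam in ("omega", "sigma"):
            rates = np.atleast_1d(fit.acceptance[fam])
            assert np.all(np.abs(rates - 0.234) < 0.15)

    def test_duplicated_individuals_get_matching_rows(self):
        rng = np.random.default_rng(5)
        Q = np.vstack([np.eye(2), np.eye(2), rng.dirichlet(np.ones(2), size=6)])
        Q = np.vstack([Q, Q[-1]])  # duplicate the last individual
        omega = np.array([[0.08, 0.04], [0.04, 0.1]])
        chat = Q @ omega @ Q.T
        obs = chat + rng.normal(0, 5e-4, chat.shape)
        obs = (obs + obs.T) / 2
        fit = fit_structf4(obs, K=2, settings=McmcSettings(iterations=800, burnin=400, seed=2, n_restarts=2))
        dup = np.abs(fit.params.Q[-1] - fit.params.Q[-2]).sum()
        assert dup < 0.02

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(0.05, 0.01, (8, 8))
        obs = (obs + obs.T) / 2
        st = McmcSettings(iterations=300, burnin=150, seed=11, n_restarts=2)
        f1 = fit_structf4(obs, K=2, settings=st)
        f2 = fit_structf4(obs, K=2, settings=st)
        assert np.array_equal(f1.trace, f2.trace)
        assert np.array_equal(f1.params.Q, f2.params.Q)


class TestMds:
    def make_coan(self, values, labels):
        return CoancestryMatrix(values, labels, outgroup="O")

    def test_identical_individuals_collapse_to_origin(self):
        c = self.make_coan(np.full((5, 5), 0.3), [f"s{i}" for i in range(5)])
        coords, eigvals = mds(c)
        assert np.abs(coords.to_numpy()).max() < 1e-9

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0.1, 0.02, (8, 8))
        c = self.make_coan((v + v.T) / 2, [f"s{i}" for i in range(8)])
        _, eigvals = mds(c)
        assert np.all(np.diff(eigvals) <= 1e-12)

    def test_exclusion_removes_labels(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0.1, 0.02, (6, 6))
        c = self.make_coan((v + v.T) / 2, [f"s{i}" for i in range(6)])
        coords, _ = mds(c, exclude_labels=["s0"])
        assert "s0" not in coords.index

    def test_two_clusters_separate_on_first_axis(self, small_star_panel):
        from paleodrift.simulate import Branch, DemographicModel, simulate_panel
        import pandas as pd

        model = DemographicModel(
            populations=["R", "S", "P1", "P2", "O"],
            branches=[
                Branch("R", "O", 0.05),
                Branch("R", "S", 0.0),
                Branch("S", "P1", 0.1),
                Branch("S", "P2", 0.1),
            ],
        )
        rows, ids = [], []
        for g, pop in enumerate(["P1", "P2"]):
            for i in range(10):
                rows.append({p: 1.0 if p == pop else 0.0 for p in ["P1", "P2", "O"]})
                ids.append(f"{pop}_{i}")
        rows.append({"P1": 0.0, "P2": 0.0, "O": 1.0})
        ids.append("out")
        panel = simulate_panel(model, pd.DataFrame(rows, index=ids), n_sites=20_000, seed=9)
        c = coancestry(panel.calls, "out")
        coords, _ = mds(c)
        axis1 = coords["MDS1"]
        g1 = axis1[[i for i in coords.index if i.startswith("P1")]]
        g2 = axis1[[i for i in coords.index if i.startswith("P2")]]
        within_sd = max(g1.std(), g2.std())
        assert abs(g1.mean() - g2.mean()) > 5 * within_sd
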