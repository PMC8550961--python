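"""Polarization, conditioning filters, LD pruning and error-rate estimation."""

import numpy as np
import pandas as pd
import pytest

from paleodrift.panel import (
    OutgroupConsensus,
    SitePanel,
    estimate_error_rate,
    filter_sites,
    ld_prune,
    polarize_with_outgroup,
)

from conftest import make_calls, make_sites, random_calls
from _oracles import oracle_ld_prune


def outgroup_obs(per_site):
    """Build S x 7 observation array from lists like ['A']*7 or ['A']*5+['C']*2."""
    S = len(per_site)
    arr = np.full((S, 7), "", dtype="<U1")
    for s, obs in enumerate(per_site):
        for g, b in enumerate(obs):
            arr[s, g] = b
    return arr


class TestPolarization:
    def setup_method(self):
        # panel with ancestral A / derived C at four sites
        self.calls = make_calls([[0, 1, 0, 1], [1, 0, 1, 0]])

    def test_majority_rule_boundaries(self):
        og = OutgroupConsensus(outgroup_obs([
            ["A"] * 7,               # unanimous -> kept, ancestral A
            ["A"] * 5 + ["C"] * 2,   # exactly 2 of 7 alternative -> kept
            ["A"] * 4 + ["C"] * 3,   # 3 of 7 -> dropped
            [],                      # no data -> dropped
        ]))
        oriented, report = polarize_with_outgroup(self.calls, og)
        assert oriented.n_sites == 2
        assert list(report.dropped_index) == [2, 3]
        assert report.reasons == ["outgroup majority rule failed", "no outgroup"]
        # orientation unchanged: majority allele equals current ancestral
        assert np.array_equal(oriented.data, self.calls.data[:, :2])

    def test_consensus_matching_derived_flips_calls(self):
        og = OutgroupConsensus(outgroup_obs([["C"] * 7] * 4))
        oriented, report = polarize_with_outgroup(self.calls, og)
        assert oriented.n_sites == 4
        assert np.array_equal(oriented.data, 1 - self.calls.data)
        tab = oriented.sites.table
        assert (tab["ancestral"] == "C").all() and (tab["derived"] == "A").all()

    def test_third_allele_site_dropped(self):
        og = OutgroupConsensus(outgroup_obs([["G"] * 7, ["A"] * 7, ["A"] * 7, ["A"] * 7]))
        oriented, report = polarize_with_outgroup(self.calls, og)
        assert oriented.n_sites == 3
        assert report.reasons == ["outgroup allele not in panel"]

    def test_missing_outgroup_genomes_scale_threshold(self):
        # 4 observed genomes: floor(2*4/7) = 1 alternative allowed
        og = OutgroupConsensus(outgroup_obs([
            ["A", "A", "A", "C"],  # 1 of 4 -> kept
            ["A", "A", "C", "C"],  # 2 of 4 -> dropped
            ["A"] * 4,
            ["A"] * 4,
        ]))
        oriented, report = polarize_with_outgroup(self.calls, og)
        assert 1 in report.dropped_index and 0 not in report.dropped_index

    def test_polarization_is_idempotent(self):
        rng = np.random.default_rng(8)
        calls = random_calls(rng, 5, 40)
        obs = [["A"] * 7 if rng.random() < 0.5 else ["C"] * 7 for _ in range(40)]
        og = OutgroupConsensus(outgroup_obs(obs))
        once, rep = polarize_with_outgroup(calls, og)
        og_kept = OutgroupConsensus(
            og.observations[np.setdiff1d(np.arange(40), rep.dropped_index)]
        )
        twice, rep2 = polarize_with_outgroup(once, og_kept)
        assert len(rep2) == 0
        assert np.array_equal(once.data, twice.data)
        assert once.sites == twice.sites


class TestSiteFilters:
    def test_doubleton_rule(self):
        # 10 samples: site 0 singleton, site 1 doubleton, site 2 tripleton
        data = np.zeros((10, 3), dtype=np.int8)
        data[0, 0] = 1
        data[0:2, 1] = 1
        data[0:3, 2] = 1
        filtered, idx = filter_sites(make_calls(data), min_minor_count=2)
        assert list(idx) == [1, 2]

    def test_coverage_threshold(self):
        # site 0 covered in 7/10 (< 75%), site 1 in 8/10
        data = np.ones((10, 2), dtype=np.int8)
        data[0:3, 0] = -1
        data[0:2, 1] = -1
        filtered, idx = filter_sites(make_calls(data), min_coverage_fraction=0.75)
        assert list(idx) == [1]

    def test_transversions_only(self):
        table = pd.DataFrame(
            {
                "chrom": "1",
                "pos": [10, 20],
                "ancestral": ["A", "A"],
                "derived": ["G", "C"],  # transition, transversion
            }
        )
        calls = make_calls([[0, 1], [1, 0]])
        calls.sites = SitePanel(table)
        filtered, idx = filter_sites(calls, transversions_only=True)
        assert list(idx) == [1]

    def test_independent_filters_commute(self):
        rng = np.random.default_rng(3)
        calls = random_calls(rng, 10, 60)
        tv = rng.random(60) < 0.5
        table = calls.sites.table.copy()
        table.loc[~tv, "derived"] = "G"  # A->G transitions
        calls.sites = SitePanel(table)
        a, idx_a = filter_sites(calls, transversions_only=True)
        a2, idx_ab = filter_sites(a, min_coverage_fraction=0.8)
        b, idx_b = filter_sites(calls, min_coverage_fraction=0.8)
        b2, idx_ba = filter_sites(b, transversions_only=True)
        assert np.array_equal(a2.data, b2.data)

    def test_empty_result_allowed(self):
        filtered, idx = filter_sites(make_calls([[0, 0], [0, 0]]), min_minor_count=2)
        assert filtered.n_sites == 0 and len(idx) == 0


class TestLdPrune:
    def test_duplicated_column_pruned_once(self):
        rng = np.random.default_rng(1)
        base = (rng.random((30, 1)) < 0.5).astype(np.int8)
        noise = (rng.random((30, 4)) < 0.5).astype(np.int8)
        data = np.hstack([base, noise[:, :2], base, noise[:, 2:]])
        kept = ld_prune(make_calls(data), window_snps=6, step_snps=2)
        assert 0 in kept and 3 not in kept

    def test_independent_sites_all_kept(self):
        rng = np.random.default_rng(2)
        calls = random_calls(rng, 250, 30, missing_rate=0.0)
        kept = ld_prune(calls)
        assert len(kept) == 30

    def test_matches_exhaustive_oracle_on_correlated_panel(self):
        rng = np.random.default_rng(4)
        # build blocks of correlated sites so r2 straddles the threshold
        S, N = 40, 80
        data = np.empty((N, S), dtype=np.int8)
        base = (rng.random(N) < 0.5).astype(np.int8)
        for s in range(S):
            flip = rng.random(N) < rng.uniform(0.05, 0.5)
            data[:, s] = np.where(flip, 1 - base, base)
            if s % 7 == 0:
                base = (rng.random(N) < 0.5).astype(np.int8)
        calls = make_calls(data)
        kept = ld_prune(calls, window_snps=10, step_snps=3)
        oracle = oracle_ld_prune(data, window=10, step=3)
        assert list(kept) == oracle

    def test_tiny_window_is_identity(self):
        calls = make_calls([[0, 1, 0], [1, 1, 0]])
        assert list(ld_prune(calls, window_snps=1)) == [0, 1, 2]


class TestErrorRate:
    def test_identical_genomes_give_zero(self):
        rng = np.random.default_rng(5)
        row = (rng.random(2000) < 0.3).astype(np.int8)
        res = estimate_error_rate(row, row.copy(), make_sites(2000))
        assert res.rate == 0.0 and res.n_sites == 2000

    @pytest.mark.parametrize("e", [0.0, 1e-4, 1e-3])
    def test_injected_error_recovered(self, e):
        rng = np.random.default_rng(int(e * 1e6) + 7)
        S = 1_000_000
        modern = (rng.random(S) < 0.05).astype(np.int8)
        flips = rng.random(S) < e
        ancient = np.where(flips, 1 - modern, modern).astype(np.int8)
        res = estimate_error_rate(ancient, modern, make_sites(S))
        # flips on derived sites subtract; net excess ~ e * (1 - 2*0.05)
        expected = e * 0.9
        assert abs(res.rate - expected) <= max(3 * np.sqrt(e / S), 2e-6)

    def test_per_type_table_sums_to_total_excess(self):
        rng = np.random.default_rng(6)
        S = 5000
        modern = (rng.random(S) < 0.2).astype(np.int8)
        ancient = np.where(rng.random(S) < 0.01, 1, modern).astype(np.int8)
        res = estimate_error_rate(ancient, modern, make_sites(S))
        assert set(res.per_type.columns) >= {"ancestral", "observed", "rate"}

    def test_all_missing_ancient_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            estimate_error_rate(
                np.full(2000, -1, dtype=np.int8),
                np.zeros(2000, dtype=np.int8),
                make_sites(2000),
            )
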