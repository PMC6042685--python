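"""Behavioral statistics against enumeration and permutation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from nociquant import (
    BehaviorTable,
    ValidationError,
    bonferroni,
    fisher_exact,
    mann_whitney_u,
    run_behavior_tests,
    steel_test,
    summarize,
)


def mw_exact_oracle(x, y):
    """Two-sided Mann-Whitney p by full enumeration of control/treatment
    relabelings of the pooled sample (valid with or without ties)."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    obs = abs(ranks[len(x):].sum() - len(y) * (n + 1) / 2)
    count = total = 0
    for idx in itertools.combinations(range(n), len(y)):
        w = abs(ranks[list(idx)].sum() - len(y) * (n + 1) / 2)
        total += 1
        if w >= obs - 1e-12:
            count += 1
    return count / total


def steel_z(control, group):
    """Standardized tie-corrected rank sum of `group` within control+group."""
    pooled = np.concatenate([control, group])
    n0, n1 = len(control), len(group)
    N = n0 + n1
    ranks = sps.rankdata(pooled)
    w = ranks[n0:].sum()
    e = n1 * (N + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum()
    v = n0 * n1 / 12 * ((N + 1) - tie / (N * (N - 1)))
    return (w - e) / math.sqrt(v)


def steel_exhaustive_oracle(control, groups):
    """Exact familywise-adjusted p per contrast by enumerating every
    assignment of the pooled values to (control, group_1, ..., group_k)."""
    sizes = [len(control)] + [len(g) for g in groups]
    pooled = np.concatenate([control] + list(groups))
    n = len(pooled)
    obs = [abs(steel_z(control, g)) for g in groups]
    max_stats = []
    idx_all = set(range(n))
    for ctrl_idx in itertools.combinations(range(n), sizes[0]):
        rest = sorted(idx_all - set(ctrl_idx))
        for g1_idx in itertools.combinations(rest, sizes[1]):
            g2_idx = sorted(set(rest) - set(g1_idx))
            c = pooled[list(ctrl_idx)]
            zs = [
                abs(steel_z(c, pooled[list(g1_idx)])),
                abs(steel_z(c, pooled[g2_idx])),
            ]
            max_stats.append(max(zs))
    max_stats = np.asarray(max_stats)
    return [float((max_stats >= o - 1e-12).mean()) for o in obs]


class TestSummarize:
    def test_latency_closed_form(self):
        table = BehaviorTable(pd.DataFrame({
            "genotype": ["g"] * 3, "latency_s": [1.0, 2.0, 3.0]}))
        (s,) = summarize(table, "latency")
        assert s.mean == pytest.approx(2.0)
        assert s.se == pytest.approx(0.577, abs=5e-4)

    def test_binomial_proportion_se(self):
        # 143 responders of 191 animals: 74.9 +/- 3.1 %
        table = BehaviorTable(pd.DataFrame({
            "genotype": ["g"] * 191,
            "responded": [True] * 143 + [False] * 48}))
        (s,) = summarize(table, "response")
        assert 100 * s.mean == pytest.approx(74.9, abs=0.05)
        assert 100 * s.se == pytest.approx(3.1, abs=0.05)

    def test_all_censored_group(self):
        table = BehaviorTable(pd.DataFrame({
            "genotype": ["g"] * 4, "latency_s": [11.0] * 4}))
        (s,) = summarize(table, "latency")
        assert (s.mean, s.se, s.censored_count) == (11.0, 0.0, 4)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = np.array([3.0, 1.0, 2.0])
        assert mann_whitney_u(x, x).p_value == pytest.approx(1.0)

    def test_tiny_exact_case(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert "exact" in res.method
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_branch_matches_enumeration_exhaustively(self):
        """Every tie-free dataset with n <= 8 drawn from a few seeds agrees
        exactly with the full-enumeration oracle."""
        rng = np.random.default_rng(0)
        for nx, ny in [(2, 2), (3, 3), (4, 4), (3, 5)]:
            for _ in range(5):
                x = rng.normal(size=nx)
                y = rng.normal(size=ny)
                assert mann_whitney_u(x, y).p_value == pytest.approx(
                    mw_exact_oracle(x, y), rel=1e-12
                )

    def test_asymptotic_close_to_permutation_oracle_n30(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.5, 0.6, 30)
        y = rng.lognormal(0.8, 0.6, 30)
        res = mann_whitney_u(x, y)
        assert "asymptotic" in res.method
        # 1e5-resample permutation oracle on |W - E[W]|
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        obs = abs(ranks[30:].sum() - 30 * 61 / 2)
        perm = rng.permuted(np.tile(ranks, (100_000, 1)), axis=1)
        stat = np.abs(perm[:, 30:].sum(axis=1) - 30 * 61 / 2)
        p_oracle = (stat >= obs - 1e-12).mean()
        assert res.p_value == pytest.approx(p_oracle, abs=0.01)

    def test_censored_tie_block_handled(self):
        x = [1.0, 2.0, 11.0, 11.0, 11.0]
        y = [3.0, 11.0, 11.0, 11.0, 11.0, 11.0]
        res = mann_whitney_u(x, y)
        assert "asymptotic" in res.method  # ties force the corrected branch
        assert 0 < res.p_value <= 1


class TestSteel:
    def test_groups_identical_to_control_give_p_near_one(self):
        rng = np.random.default_rng(2)
        control = rng.lognormal(0.5, 0.6, 15)
        groups = [control.copy() for _ in range(3)]  # z == 0 per contrast
        res = steel_test(control, groups, n_resamples=5000, seed=0)
        assert all(r.p_value >= 0.9 for r in res)

    def test_k1_reduces_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.8, 1, 10)
        steel_p = steel_test(x, [y], n_resamples=40_000, seed=1)[0].p_value
        mw_p = mann_whitney_u(x, y).p_value
        # with one contrast the max-|z| permutation IS the exact MW null
        assert steel_p == pytest.approx(mw_p, abs=0.01)

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        control = rng.normal(0, 1, 4)
        groups = [rng.normal(1.2, 1, 3), rng.normal(0, 1, 3)]
        oracle = steel_exhaustive_oracle(control, groups)
        res = steel_test(control, groups, n_resamples=40_000, seed=2)
        for r, p_exact in zip(res, oracle):
            mc_se = math.sqrt(p_exact * (1 - p_exact) / 40_000)
            assert r.p_value == pytest.approx(p_exact, abs=max(3 * mc_se, 0.005))

    def test_asymptotic_variant_tracks_permutation(self):
        rng = np.random.default_rng(5)
        control = rng.lognormal(0.5, 0.6, 20)
        groups = [rng.lognormal(0.9, 0.6, 20), rng.lognormal(0.5, 0.6, 20)]
        perm = steel_test(control, groups, n_resamples=40_000, seed=3)
        asym = steel_test(control, groups, method="asymptotic")
        for p, a in zip(perm, asym):
            assert a.p_value == pytest.approx(p.p_value, abs=0.05)

    def test_empty_group_list_raises(self):
        with pytest.raises(ValidationError):
            steel_test([1.0, 2.0], [])


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # response counts reconstructed from printed n and %:
        # control 48/154 responders vs mutant 143/191
        table = np.array([[48, 106], [143, 48]])
        res = fisher_exact(table)
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        rv = sps.hypergeom(n, r1, c1)
        p_obs = rv.pmf(table[0, 0])
        support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
        p_oracle = rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-7)].sum()
        assert res.p_value == pytest.approx(p_oracle, rel=1e-6)
        assert res.p_value < 0.001

    def test_row_swap_symmetry(self):
        t = [[7, 2], [3, 9]]
        assert fisher_exact(t).p_value == pytest.approx(
            fisher_exact(t[::-1]).p_value
        )

    def test_transpose_invariance(self):
        t = np.array([[7, 2], [3, 9]])
        assert fisher_exact(t).p_value == pytest.approx(fisher_exact(t.T).p_value)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValidationError):
            fisher_exact([[0, 0], [3, 4]])


class TestBonferroni:
    def test_scalar_cases(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.6, 2) == 1.0

    def test_vector_matches_scalar(self):
        p = [0.01, 0.2, 0.5]
        np.testing.assert_allclose(
            bonferroni(p, 3), [bonferroni(v, 3) for v in p]
        )

    def test_m_smaller_than_count_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni([0.1, 0.2], 1)


class TestRunBehaviorTests:
    def _table(self):
        rng = np.random.default_rng(6)
        rows = []
        for g, (mu, p) in {"w1118": (0.5, 0.3), "mutA": (1.2, 0.7),
                           "mutB": (0.5, 0.35)}.items():
            for i in range(25):
                rows.append({
                    "genotype": g,
                    "latency_s": min(float(rng.lognormal(mu, 0.5)), 11.0),
                    "responded": bool(rng.random() < p),
                })
        return BehaviorTable(pd.DataFrame(rows))

    def test_steel_driver_flags_shifted_group(self):
        res = run_behavior_tests(self._table(), "latency", "w1118", "steel",
                                 n_resamples=5000, seed=0)
        p = dict(zip(res["group"], res["p_value"]))
        assert p["mutA"] < 0.01 < p["mutB"]

    def test_fisher_driver_applies_bonferroni(self):
        res = run_behavior_tests(self._table(), "response", "w1118", "fisher")
        assert (res["adjustment"] == "bonferroni(2)").all()

    def test_unknown_control_rejected(self):
        with pytest.raises(ValidationError):
            run_behavior_tests(self._table(), "latency", "nope", "mw")
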