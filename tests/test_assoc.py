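"""Partial Spearman, BH adjustment, Mann-Kendall, Wilcoxon and ORA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ferroflux as ff
from ferroflux.assoc import mann_kendall_trend, wilcoxon_rank_sum, hypergeom_ora
from ferroflux.containers import FerrofluxError


# ------------------------------------------------------------ partial Spearman


def test_partial_spearman_hand_example():
    rho, _ = ff.partial_spearman([1, 2, 3], [3, 1, 2])
    assert rho == pytest.approx(-0.5)


def test_reduces_to_spearman_without_covariates(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    rho, p = ff.partial_spearman(x, y)
    ref = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic, abs=1e-10)


def test_partial_spearman_matches_rank_residual_brute_force(rng):
    x = rng.normal(size=40)
    z = rng.normal(size=(40, 2))
    y = z @ [1.0, -1.0] + rng.normal(size=40)
    rho, _ = ff.partial_spearman(x, y, z)
    # brute force: rank everything, regress out [1, ranked z], correlate
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rz = np.column_stack([np.ones(40)] + [stats.rankdata(z[:, j]) for j in range(2)])
    ex = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
    ey = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
    ref = ex @ ey / (np.linalg.norm(ex) * np.linalg.norm(ey))
    assert rho == pytest.approx(ref, abs=1e-10)


def test_confounder_adjustment_shrinks_rho(rng):
    z = rng.normal(size=300)
    x = z + rng.normal(size=300)
    y = z + rng.normal(size=300)
    plain, _ = ff.partial_spearman(x, y)
    partial, _ = ff.partial_spearman(x, y, z)
    assert abs(partial) < abs(plain)


def test_partial_spearman_null_p_uniform(rng):
    ps = []
    z = rng.normal(size=50)
    for _ in range(300):
        x = 0.5 * z + rng.normal(size=50)
        y = 0.5 * z + rng.normal(size=50)
        # x and y depend on z but are conditionally independent
        ps.append(ff.partial_spearman(x, y, z)[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_partial_spearman_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    z = rng.normal(size=20)
    r1, p1 = ff.partial_spearman(x, y, z)
    r2, p2 = ff.partial_spearman(np.exp(x), y**3, z)
    assert r1 == pytest.approx(r2, abs=1e-10)
    r3, _ = ff.partial_spearman(y, x, z)
    assert r1 == pytest.approx(r3, abs=1e-10)


def test_partial_spearman_errors():
    with pytest.raises(FerrofluxError):
        ff.partial_spearman([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(FerrofluxError):
        ff.partial_spearman([1, 2, 3], [3, 1, 2], np.ones((3, 2)))


# ------------------------------------------------------------ BH adjustment


def _bh_oracle(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_worked_example():
    np.testing.assert_allclose(
        ff.bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05], atol=1e-12
    )
    np.testing.assert_allclose(ff.bh_adjust([1.0, 1.0, 1.0]), 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(1, 40))
def test_bh_matches_step_up_oracle(seed, m):
    p = np.random.default_rng(seed).uniform(size=m)
    np.testing.assert_allclose(ff.bh_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(FerrofluxError):
        ff.bh_adjust([0.5, 1.2])


# ------------------------------------------------------------ Mann-Kendall


def test_mann_kendall_perfect_trend():
    res = mann_kendall_trend([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.S == 6 and res.tau == pytest.approx(1.0)
    rev = mann_kendall_trend([4, 3, 2, 1], [1, 2, 3, 4])
    assert rev.S == -6 and rev.tau == pytest.approx(-1.0)


def test_mann_kendall_tau_matches_scipy(rng):
    groups = rng.integers(0, 4, size=40)
    values = rng.normal(size=40)
    res = mann_kendall_trend(values, groups)
    ref = stats.kendalltau(groups, values)
    assert res.tau == pytest.approx(ref.statistic, abs=1e-12)


def test_mann_kendall_null_p_uniform(rng):
    ps = []
    groups = np.repeat([0, 1, 2, 3], 10)
    for _ in range(500):
        ps.append(mann_kendall_trend(rng.normal(size=40), groups).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_mann_kendall_single_group_errors():
    with pytest.raises(FerrofluxError):
        mann_kendall_trend([1.0, 2.0], [1, 1])


# ------------------------------------------------------------ Wilcoxon


def test_wilcoxon_tiny_exact():
    U, p = wilcoxon_rank_sum([1, 2], [3, 4])
    assert U == 0 and p == pytest.approx(1 / 3)


def test_wilcoxon_identical_samples():
    _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
    assert p == pytest.approx(1.0)


def test_wilcoxon_normal_close_to_exact(rng):
    for _ in range(10):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p_exact = wilcoxon_rank_sum(a, b, mode="exact")
        _, p_norm = wilcoxon_rank_sum(a, b, mode="normal")
        assert abs(p_exact - p_norm) < 0.02


# ------------------------------------------------------------ ORA


def test_ora_exact_enumeration_oracle():
    universe = {f"g{i}" for i in range(20)}
    gene_set = {f"g{i}" for i in range(5)}
    selected = {"g0", "g1", "g2", "g10", "g11"}
    res = hypergeom_ora(selected, {"s": gene_set}, universe)
    # exhaustive enumeration over all C(20,5) draws of the selected set
    count = sum(
        len(set(draw) & gene_set) >= 3
        for draw in itertools.combinations(sorted(universe), 5)
    )
    total = 15504
    assert count / total == pytest.approx(1126 / 15504)
    assert res["p"].iloc[0] == pytest.approx(1126 / 15504, abs=1e-12)


def test_ora_degenerate_cases():
    universe = {f"g{i}" for i in range(10)}
    res = hypergeom_ora(set(), {"s": {"g0", "g1"}}, universe)
    assert res["p"].iloc[0] == pytest.approx(1.0)
    res = hypergeom_ora(universe, {"s": {"g0", "g1"}}, universe)
    assert res["overlap"].iloc[0] == 2 and res["p"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(FerrofluxError):
        hypergeom_ora(set(), {"s": set()}, set())


def test_ora_bonferroni_and_gmt(tmp_path):
    universe = {f"g{i}" for i in range(30)}
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("s1\tdesc\tg0\tg1\tg2\ns2\tdesc\tg5\tg6\n")
    sets = ff.read_gmt(gmt)
    assert sets == {"s1": {"g0", "g1", "g2"}, "s2": {"g5", "g6"}}
    res = hypergeom_ora({"g0", "g1", "g2"}, sets, universe)
    assert np.all(res["p_adjusted"] >= res["p"] - 1e-15)
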