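"""O-PLS fitting, prediction, cross-validation, permutation validation,
VIP and feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ferroflux as ff
from ferroflux.containers import FerrofluxError
from ferroflux.opls import permutation_test, vip


def test_univariate_linear_identity(rng):
    x = rng.normal(size=(25, 1))
    y = 2.0 * x.ravel()
    m = ff.fit_opls(x, y, n_orth=0)
    assert m.r2y == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(ff.predict(m, x), y, atol=1e-10)


def test_orthogonal_variation_removed(rng):
    y = rng.normal(size=40)
    y -= y.mean()
    z = rng.normal(size=40)
    z -= z.mean()
    z -= z @ y / (y @ y) * y  # orthogonalize z against y
    X = np.column_stack([y, z])
    m = ff.fit_opls(X, y, n_orth=1, scaling="none")
    # after filtering, the predictive weight on the orthogonal column vanishes
    assert abs(m.w[1]) < 1e-6


def test_matches_pls1_oracle(rng):
    from sklearn.cross_decomposition import PLSRegression

    X = rng.normal(size=(20, 5))
    y = rng.normal(size=20)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    m = ff.fit_opls(Xs, y, n_orth=0, scaling="none")
    ref = PLSRegression(n_components=1, scale=False).fit(Xs, y)
    np.testing.assert_allclose(
        ff.predict(m, Xs), ref.predict(Xs).ravel(), atol=1e-10
    )


def test_predict_mean_row_and_duplicates(rng):
    X = rng.normal(size=(30, 4))
    y = X @ rng.normal(size=4) + 0.1 * rng.normal(size=30)
    m = ff.fit_opls(X, y, n_orth=1)
    assert ff.predict(m, X.mean(0, keepdims=True))[0] == pytest.approx(y.mean())
    dup = ff.predict(m, np.vstack([X[3], X[3]]))
    assert dup[0] == dup[1]


def test_prediction_invariant_to_feature_order(rng):
    X = pd.DataFrame(rng.normal(size=(25, 6)), columns=[f"f{j}" for j in range(6)])
    y = rng.normal(size=25)
    m = ff.fit_opls(X, y, n_orth=1)
    shuffled = X[["f3", "f0", "f5", "f1", "f4", "f2"]]
    np.testing.assert_allclose(ff.predict(m, shuffled), ff.predict(m, X), atol=1e-12)


def test_orthogonal_scores_orthogonal_to_predictive(rng):
    X = rng.normal(size=(40, 10))
    y = X @ rng.normal(size=10) + rng.normal(size=40)
    m = ff.fit_opls(X, y, n_orth=2)
    for i in range(m.n_orth_used):
        assert abs(m.T_o[:, i] @ m.t) <= 1e-8 * np.linalg.norm(m.T_o[:, i]) * np.linalg.norm(m.t)
    assert np.linalg.norm(m.w) == pytest.approx(1.0, abs=1e-12)


def test_fit_input_validation(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(FerrofluxError):
        ff.fit_opls(X, np.ones(10))  # constant y
    Xn = X.copy()
    Xn[0, 0] = np.nan
    with pytest.raises(FerrofluxError):
        ff.fit_opls(Xn, rng.normal(size=10))
    with pytest.raises(FerrofluxError):
        ff.fit_opls(X, rng.normal(size=10), n_orth=5)  # n_orth >= rank


def test_q2_noiseless_and_bounded(rng):
    X = rng.normal(size=(30, 3))
    y = X @ np.array([1.0, -2.0, 0.5])
    # with p - 1 orthogonal components the single predictive component
    # captures the full noiseless relation
    assert ff.q2_loocv(X, y, n_orth=2) > 0.99
    noisy = ff.q2_loocv(X, rng.normal(size=30), n_orth=1)
    assert noisy <= 1.0


def test_q2_null_median_negative(rng):
    q2s = [
        ff.q2_loocv(rng.normal(size=(40, 20)), rng.normal(size=40), n_orth=1)
        for _ in range(40)
    ]
    assert np.median(q2s) < 0


def test_permutation_detects_planted_signal(rng):
    X = rng.normal(size=(30, 8))
    y = X @ rng.normal(size=8)  # strong deterministic signal
    res = permutation_test(X, y, n_orth=1, n_permutations=99, seed=0)
    assert res.p_q2y == pytest.approx(1 / 100)
    assert len(res.null_q2y) == 99 and len(res.null_r2y) == 99


def test_permutation_null_p_uniform(rng):
    # type-I calibration at a reduced scale; the acceptance suite runs the
    # full 400-replicate version
    ps = []
    for _ in range(60):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        ps.append(permutation_test(X, y, 1, 99, seed=int(rng.integers(2**31)),
                                   cv=5).p_q2y)
    assert np.mean(np.asarray(ps) < 0.2) < 0.45  # coarse super-uniformity check


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_vip_mean_square_one(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(20, 7))
    y = X @ rng.normal(size=7) + rng.normal(size=20)
    m = ff.fit_opls(X, y, n_orth=1)
    v = vip(m)
    assert np.mean(v**2) == pytest.approx(1.0, abs=1e-10)


def test_vip_identical_copies_all_one(rng):
    y = rng.normal(size=25)
    X = np.tile(y[:, None], (1, 5))
    m = ff.fit_opls(X, y, n_orth=0)
    np.testing.assert_allclose(vip(m), 1.0, atol=1e-10)


def test_vip_flags_informative_feature(rng):
    y = rng.normal(size=100)
    X = rng.normal(size=(100, 5))
    X[:, 2] = y + 0.1 * rng.normal(size=100)
    m = ff.fit_opls(X, y, n_orth=0)
    assert np.argmax(vip(m)) == 2
    assert vip(m, variant="total").shape == (5,)


def test_select_features_rule(rng):
    y = rng.normal(size=60)
    X = rng.normal(size=(60, 10))
    X[:, 0] = y
    m = ff.fit_opls(X, y, n_orth=0)
    table = ff.select_features(X, y, m)
    assert table["selected"].iloc[0]
    assert table["pFDR"].iloc[0] < 1e-10
    # explicit rule check: pFDR in the relaxed band selects only with VIP > 1
    sel = (table["pFDR"] < 0.05) | ((table["pFDR"] < 0.10) & (table["vip"] > 1.0))
    assert (table["selected"] == sel).all()


def test_choose_n_orth_returns_nonnegative(rng):
    X = rng.normal(size=(40, 6))
    y = X @ rng.normal(size=6) + rng.normal(size=40)
    k = ff.choose_n_orth(X, y, max_orth=3)
    assert 0 <= k <= 3
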