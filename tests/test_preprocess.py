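"""Filtering, transforms, quartiles, diversity, ordination and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ferroflux as ff
from ferroflux.containers import DistanceMatrix, FerrofluxError, OmicsBlock


def _block(values, kind="counts", name="b"):
    values = np.asarray(values)
    return OmicsBlock(
        name,
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(values.shape[0])],
            columns=[f"f{j}" for j in range(values.shape[1])],
        ),
        kind=kind,
    )


# ---------------------------------------------------------------- filtering


def test_filter_keeps_abundant_prevalent_feature():
    rel = np.array([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
    out = ff.filter_features(_block(rel, kind="intensity"), 0.2, 0.2)
    assert list(out.feature_ids) == ["f0", "f1"]


def test_filter_drops_low_prevalence_feature():
    rel = np.array([[0.25, 0.75], [0.01, 0.99], [0.01, 0.99]])
    out = ff.filter_features(_block(rel, kind="intensity"), 0.2, 0.5)
    assert list(out.feature_ids) == ["f1"]


def test_filter_matches_brute_force_rule(rng):
    counts = rng.integers(0, 50, size=(5, 4))
    counts[0, 0] = 0
    block = _block(counts)
    out = ff.filter_features(block, 0.15, 0.4)
    rel = counts / counts.sum(axis=1, keepdims=True)
    expected = [
        f"f{j}"
        for j in range(4)
        if np.mean(rel[:, j] > 0.15) >= 0.4
    ]
    assert list(out.feature_ids) == expected


def test_filter_idempotent_and_warns_on_empty(rng):
    counts = rng.integers(1, 10, size=(4, 6))
    block = _block(counts)
    once = ff.filter_features(block, 0.1, 0.25)
    twice = ff.filter_features(once, 0.1, 0.25)
    pd.testing.assert_frame_equal(once.data, twice.data)
    with pytest.warns(UserWarning):
        empty = ff.filter_features(block, 0.999, 1.0)
    assert empty.n_features == 0


# ---------------------------------------------------------------- transforms


def test_relative_abundance_closure():
    out = ff.relative_abundance(_block([[2, 2], [0, 5]]))
    np.testing.assert_allclose(out.data.to_numpy(), [[0.5, 0.5], [0.0, 1.0]])
    with pytest.raises(FerrofluxError, match="s1"):
        ff.relative_abundance(_block([[1, 1], [0, 0]]))


def test_log10_values_and_domain_error():
    out = ff.log10_transform(_block([[100, 1]], kind="intensity"), pseudocount=0)
    np.testing.assert_allclose(out.data.to_numpy(), [[2.0, 0.0]])
    out = ff.log10_transform(_block([[0, 9]], kind="intensity"), pseudocount=1)
    np.testing.assert_allclose(out.data.to_numpy(), [[0.0, 1.0]])
    with pytest.raises(FerrofluxError):
        ff.log10_transform(_block([[0, 1]], kind="intensity"), pseudocount=0)


def test_zscore_moments(rng):
    block = _block(rng.normal(size=(10, 4)), kind="intensity")
    out = ff.zscore(block)
    np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.data.std(axis=0, ddof=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(ff.zscore(_block([[1], [2], [3]], kind="intensity"))
                               .data.to_numpy().ravel(), [-1, 0, 1])


def test_zscore_drops_constant_feature():
    vals = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.warns(UserWarning):
        out = ff.zscore(_block(vals, kind="intensity"))
    assert list(out.feature_ids) == ["f1"]


# ---------------------------------------------------------------- quartiles


def test_quartiles_symmetric_case():
    q = ff.assign_quartiles(np.arange(1, 9))
    assert list(q) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_quartiles_degenerate_all_equal():
    with pytest.warns(UserWarning):
        q = ff.assign_quartiles(np.ones(8))
    assert set(q) == {"Q1"}


def test_quartile_sizes_balanced(rng):
    q = ff.assign_quartiles(rng.uniform(size=1000))
    sizes = q.value_counts()
    assert all(abs(sizes[label] - 250) <= 1 for label in ["Q1", "Q2", "Q3", "Q4"])
    with pytest.raises(FerrofluxError):
        ff.assign_quartiles([1, 2, 3])


# ---------------------------------------------------------------- diversity


def test_shannon_and_observed():
    out = ff.alpha_diversity(_block([[10, 10, 10, 10]]))
    assert out["shannon"].iloc[0] == pytest.approx(np.log(4), abs=1e-12)
    assert out["observed_species"].iloc[0] == 4


def test_chao1_forms():
    sample = _block([[5, 4, 1, 1, 2, 2]])
    classic = ff.alpha_diversity(sample, chao1_bias_corrected=False)
    assert classic["chao1"].iloc[0] == pytest.approx(7.0)
    no_singletons = ff.alpha_diversity(_block([[5, 4, 2, 2]]))
    assert no_singletons["chao1"].iloc[0] == pytest.approx(4.0)
    bc = ff.alpha_diversity(sample)
    assert bc["chao1"].iloc[0] >= bc["observed_species"].iloc[0]


def test_beta_diversity_metrics(rng):
    assert ff.beta_diversity(_block([[1, 0], [0, 1]]), "canberra").values[0, 1] == 2.0
    block = _block(rng.integers(0, 20, size=(5, 6)) + 1)
    for metric in ("canberra", "bray_curtis", "euclidean"):
        D = ff.beta_diversity(block, metric)
        assert np.allclose(np.diag(D.values), 0.0)
    with pytest.raises(FerrofluxError):
        ff.beta_diversity(block, "unifrac")


def test_bray_curtis_zero_sample_policy():
    with pytest.warns(UserWarning):
        D = ff.beta_diversity(_block([[2, 2], [0, 0]]), "bray_curtis")
    assert D.values[0, 1] == 1.0


def test_beta_diversity_matches_skbio(rng):
    skbio_div = pytest.importorskip("skbio.diversity")
    vals = rng.integers(1, 30, size=(6, 8)).astype(float)
    D = ff.beta_diversity(_block(vals.astype(int)), "bray_curtis")
    ref = skbio_div.beta_diversity("braycurtis", vals).data
    np.testing.assert_allclose(D.values, ref, atol=1e-12)


# ---------------------------------------------------------------- ordination


def test_pcoa_recovers_planar_coordinates(rng):
    pts = rng.normal(size=(12, 2))
    from scipy.spatial.distance import pdist, squareform
    D = DistanceMatrix(pd.Index([f"s{i}" for i in range(12)]),
                       squareform(pdist(pts)))
    ord_ = ff.pcoa(D, k=2)
    # classical scaling reproduces Euclidean configurations up to
    # rotation/reflection; Procrustes removes that
    from scipy.spatial import procrustes
    _, _, disparity = procrustes(pts - pts.mean(0), ord_.scores.to_numpy())
    assert disparity < 1e-16
    assert np.all(np.diff(ord_.eigenvalues) <= 1e-9)


def test_pcoa_collinear_points():
    pts = np.array([[0.0], [1.0], [2.0]])
    from scipy.spatial.distance import pdist, squareform
    D = DistanceMatrix(pd.Index(["a", "b", "c"]), squareform(pdist(pts)))
    ord_ = ff.pcoa(D, k=2)
    assert ord_.eigenvalues[1] < 1e-10


# ---------------------------------------------------------------- PERMANOVA


def _distance_from(points):
    from scipy.spatial.distance import pdist, squareform
    ids = pd.Index([f"s{i}" for i in range(len(points))])
    return DistanceMatrix(ids, squareform(pdist(points)))


def test_permanova_separated_groups_minimal_p():
    pts = np.vstack([np.zeros((10, 2)), np.full((10, 2), 50.0)])
    pts += np.random.default_rng(0).normal(scale=1e-6, size=pts.shape)
    D = _distance_from(pts)
    res = ff.permanova(D, ["a"] * 10 + ["b"] * 10, n_permutations=199, seed=1)
    assert res.p == pytest.approx(1 / 200)
    assert res.R2 > 0.99


def test_permanova_matches_exhaustive_oracle(rng):
    pts = rng.normal(size=(6, 3))
    D = _distance_from(pts)
    groups = ["a", "a", "a", "b", "b", "b"]
    res = ff.permanova(D, groups, exact=True)

    # independent brute force from the one-way partitioning definition
    D2 = D.values**2
    def brute_f(codes):
        n = len(codes)
        ss_t = D2.sum() / (2 * n)
        ss_w = 0.0
        for g in set(codes):
            idx = [i for i, c in enumerate(codes) if c == g]
            ss_w += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return ((ss_t - ss_w) / 1) / (ss_w / 4)

    f_obs = brute_f(groups)
    assert res.pseudo_F == pytest.approx(f_obs, rel=1e-12)
    perms = set(itertools.permutations(groups))
    p_exact = np.mean([brute_f(list(p)) >= f_obs - 1e-12 for p in perms])
    assert res.p == pytest.approx(p_exact, rel=1e-12)


def test_permanova_matches_skbio(rng):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    pts = rng.normal(size=(12, 3))
    pts[:6] += 1.5
    D = _distance_from(pts)
    groups = ["a"] * 6 + ["b"] * 6
    mine = ff.permanova(D, groups, n_permutations=999, seed=0)
    ref = skbio_stats.permanova(
        skbio_stats.DistanceMatrix(D.values, ids=list(D.sample_ids)), groups,
        permutations=999,
    )
    assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)


def test_permanova_single_group_errors():
    D = _distance_from(np.random.default_rng(0).normal(size=(4, 2)))
    with pytest.raises(FerrofluxError):
        ff.permanova(D, ["a"] * 4, n_permutations=9)
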