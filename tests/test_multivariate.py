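"""Standardized PCA, MLR with variable impact, simple fits, mean ellipses.

PCA loadings are checked against two independent oracles: a brute-force
characteristic-polynomial eigensolve for 3x3 correlation matrices, and
scikit-learn's SVD-based PCA.  MLR coefficients are checked against the
textbook normal-equations solution.
"""

import numpy as np
import pandas as pd
import pytest

from polyuptake.multivariate import (
    TrendSign,
    _orient_components,
    mean_confidence_ellipse,
    mlr_fit,
    pca,
    simple_fit,
    standardize,
    transform_zeta,
)

# ---------------------------------------------------------------- standardize


def test_standardize_basic_and_idempotent():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    std, means, sds = standardize(df)
    assert np.allclose(std["a"], [-1, 0, 1])
    assert means["a"] == 2.0 and sds["a"] == 1.0
    std2, _, _ = standardize(std)
    assert np.allclose(std2.to_numpy(), std.to_numpy())


def test_standardize_rejects_constant_column():
    df = pd.DataFrame({"a": [1.0, 2, 3], "flat": [7.0, 7, 7]})
    with pytest.raises(ValueError, match="flat"):
        standardize(df)


def test_standardize_drops_incomplete_rows(caplog):
    df = pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [1.0, 0, 2, 5]})
    with caplog.at_level("INFO"):
        std, _, _ = standardize(df)
    assert len(std) == 3
    assert "dropped 1" in caplog.text


def test_transform_zeta_involution():
    assert transform_zeta(-45.0) == 45.0
    assert transform_zeta(0.0) == 0.0
    assert transform_zeta(transform_zeta(-12.5)) == -12.5


# ----------------------------------------------------------------------- PCA


def test_pca_two_perfectly_correlated_variables():
    rng = np.random.default_rng(0)
    a = rng.normal(size=40)
    df = pd.DataFrame({"a": a, "b": 2 * a + 1})
    std, _, _ = standardize(df)
    res = pca(std)
    assert res.explained_fraction[0] == pytest.approx(1.0)
    assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
    assert res.zero_variance_components == [1]


from tests_oracles import brute_force_eig3 as _brute_force_eig3


@pytest.mark.parametrize("seed", range(100))
def test_pca_matches_characteristic_polynomial_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    std, _, _ = standardize(df)
    res = pca(std)
    corr = np.corrcoef(std.to_numpy().T)
    lams, vecs = _brute_force_eig3(corr)
    assert np.allclose(res.eigenvalues, lams, atol=1e-8)
    assert np.allclose(res.loadings, _orient_components(vecs), atol=1e-8)


def test_pca_matches_sklearn(default_library):
    sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
    records, *_ = default_library
    df = pd.DataFrame(
        {
            "c": [r.design.monomer_conc for r in records],
            "x": [r.x_sty for r in records],
            "Mn": [r.mn for r in records],
            "d": [r.d_dls for r in records],
            "-z": [r.minus_z for r in records],
        }
    )
    std, _, _ = standardize(df)
    res = pca(std)
    sk = sklearn_pca(n_components=5).fit(std.to_numpy())
    assert np.allclose(
        res.loadings, _orient_components(sk.components_.T), atol=1e-8
    )
    assert np.allclose(res.explained_fraction, sk.explained_variance_ratio_,
                       atol=1e-8)


def test_pca_reconstruction_and_orthonormality(default_library):
    records, *_ = default_library
    df = pd.DataFrame(
        {"x": [r.x_sty for r in records], "Mn": [r.mn for r in records],
         "d": [r.d_dls for r in records], "-z": [r.minus_z for r in records]}
    )
    std, _, _ = standardize(df)
    res = pca(std)
    assert np.allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-8)
    assert np.allclose(res.scores @ res.loadings.T, std.to_numpy(), atol=1e-8)
    assert res.explained_fraction.sum() == pytest.approx(1.0)
    assert np.all(np.diff(res.explained_fraction) <= 1e-12)


def test_pca_invariant_to_variable_ordering(default_library):
    records, *_ = default_library
    df = pd.DataFrame(
        {"x": [r.x_sty for r in records], "Mn": [r.mn for r in records],
         "d": [r.d_dls for r in records]}
    )
    std, _, _ = standardize(df)
    res_a = pca(std)
    res_b = pca(std[["d", "x", "Mn"]])
    perm = [res_b.variable_names.index(v) for v in res_a.variable_names]
    assert np.allclose(res_a.loadings, res_b.loadings[perm, :], atol=1e-8)


# ----------------------------------------------------------------------- MLR


def test_mlr_single_predictor_impact_is_one(rng):
    x = rng.normal(size=30)
    df = pd.DataFrame({"x": x, "y": 2 * x + rng.normal(size=30)})
    fit = mlr_fit(df, ["x"], "y")
    assert fit.impact["x"] == pytest.approx(1.0)


def test_mlr_symmetric_two_predictor_impacts():
    """Equal true coefficients on uncorrelated unit-sd predictors: I_v = 1/2."""
    rng = np.random.default_rng(7)
    a = rng.normal(size=200)
    b = rng.normal(size=200)
    # orthogonalize and standardize exactly
    b = b - a * (a @ b) / (a @ a)
    a = (a - a.mean()) / a.std(ddof=1)
    b = (b - b.mean()) / b.std(ddof=1)
    df = pd.DataFrame({"a": a, "b": b, "y": 3.0 * a + 3.0 * b + 1.0})
    fit = mlr_fit(df, ["a", "b"], "y")
    assert fit.impact["a"] == pytest.approx(0.5, abs=1e-10)
    assert fit.impact["b"] == pytest.approx(0.5, abs=1e-10)
    assert fit.rmspe == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_mlr_matches_normal_equations(seed):
    rng = np.random.default_rng(2000 + seed)
    X = rng.normal(size=(30, 3))
    beta = rng.normal(size=3)
    y = 1.5 + X @ beta + rng.normal(size=30)
    df = pd.DataFrame(X, columns=["p1", "p2", "p3"])
    df["y"] = y
    fit = mlr_fit(df, ["p1", "p2", "p3"], "y")
    Xc = np.column_stack([np.ones(30), X])
    beta_ne = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    assert fit.intercept == pytest.approx(beta_ne[0], abs=1e-8)
    for j, name in enumerate(["p1", "p2", "p3"]):
        assert fit.coefficients[name] == pytest.approx(beta_ne[j + 1], abs=1e-8)
    # residuals orthogonal to predictors and the constant
    resid = y - fit.predict(df)
    assert abs(resid.sum()) < 1e-8 * len(resid)
    for name in ["p1", "p2", "p3"]:
        assert abs(resid @ df[name]) / (np.linalg.norm(resid)
                                        * np.linalg.norm(df[name])) < 1e-8


def test_mlr_impact_invariant_to_unit_rescaling(rng):
    X = rng.normal(size=(50, 2))
    y = X @ [2.0, -1.0] + rng.normal(size=50)
    df = pd.DataFrame(X, columns=["a", "b"])
    df["y"] = y
    base = mlr_fit(df, ["a", "b"], "y")
    df2 = df.copy()
    df2["a"] = df2["a"] * 1000  # e.g. g/mol instead of kg/mol
    rescaled = mlr_fit(df2, ["a", "b"], "y")
    assert rescaled.impact["a"] == pytest.approx(base.impact["a"], rel=1e-9)


def test_mlr_square_transform(rng):
    mn = rng.uniform(100, 800, size=40)
    y = 0.001 * mn**2 + rng.normal(size=40)
    df = pd.DataFrame({"Mn": mn, "y": y})
    fit = mlr_fit(df, ["Mn"], "y", square=["Mn"])
    assert "Mn^2" in fit.coefficients
    assert fit.coefficients["Mn^2"] == pytest.approx(0.001, rel=0.05)


def test_mlr_rejects_collinear_design(rng):
    a = rng.normal(size=30)
    df = pd.DataFrame({"a": a, "b": 2 * a, "y": rng.normal(size=30)})
    with pytest.raises(ValueError, match="[Cc]ollinear"):
        mlr_fit(df, ["a", "b"], "y")


# ---------------------------------------------------------------- simple fit


def test_simple_fit_collinear_points():
    fit = simple_fit([0, 1, 2, 3], [1, 3, 5, 7])
    assert fit["r_squared"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(2.0)


def test_simple_fit_null_has_low_r_squared(rng):
    x = rng.normal(size=1000)
    y = rng.normal(size=1000)
    assert simple_fit(x, y)["r_squared"] < 0.02


def test_simple_fit_group_means():
    # grouping by nominal feed averages out within-group scatter exactly
    # group means (2, 12), (5, 18), (10, 28) lie exactly on y = 2x + 8
    groups = [0, 0, 25, 25, 50, 50]
    x = [1.0, 3.0, 4.0, 6.0, 9.0, 11.0]
    y = [10.0, 14.0, 16.0, 20.0, 26.0, 30.0]
    fit = simple_fit(x, y, group_means=True, groups=groups)
    assert fit["n"] == 3
    assert fit["r_squared"] == pytest.approx(1.0)


def test_simple_fit_requires_three_points():
    with pytest.raises(ValueError, match=">= 3"):
        simple_fit([1, 2], [1, 2])


# ------------------------------------------------------------------ ellipses


def test_ellipse_isotropic_cloud_is_round(rng):
    xy = rng.normal(size=(10000, 2))
    ell = mean_confidence_ellipse(xy[:, 0], xy[:, 1], level=0.95)
    a, b = ell.semi_axes
    assert abs(a - b) / a < 0.05
    assert ell.trend_sign is TrendSign.NONE


def test_ellipse_level_monotonicity(rng):
    xy = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.4], [0.0, 0.8]])
    low = mean_confidence_ellipse(xy[:, 0], xy[:, 1], level=0.95)
    high = mean_confidence_ellipse(xy[:, 0], xy[:, 1], level=0.999)
    assert high.semi_axes[0] > low.semi_axes[0]
    assert high.semi_axes[1] > low.semi_axes[1]
    # same data: the wider ellipse strictly contains the boundary of the narrow
    for t in np.linspace(0, 2 * np.pi, 36):
        ang = np.radians(low.angle_deg)
        u = low.semi_axes[0] * np.cos(t)
        v = low.semi_axes[1] * np.sin(t)
        pt = (
            low.center[0] + u * np.cos(ang) - v * np.sin(ang),
            low.center[1] + u * np.sin(ang) + v * np.cos(ang),
        )
        assert high.contains(pt)


def test_ellipse_perfect_correlation_degenerates():
    x = np.linspace(0, 1, 50)
    ell = mean_confidence_ellipse(x, 2 * x + 1)
    assert ell.trend_sign is TrendSign.POSITIVE
    assert ell.semi_axes[1] == pytest.approx(0.0, abs=1e-8)


def test_ellipse_rejects_degenerate_and_bad_level():
    with pytest.raises(ValueError):
        mean_confidence_ellipse([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        mean_confidence_ellipse([1, 2, 3], [1, 2, 3.5], level=1.5)
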