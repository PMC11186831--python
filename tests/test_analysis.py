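import numpy as np
import pandas as pd
import pytest

import divergene as dg
from divergene.analysis import (
    EigenScaledPCA,
    _PipelineKernel,
    case_control_direction,
    gmm_pvalues,
    projected_loadings,
)
from divergene.lbf import LBFTransformer


def correlation_pca_oracle(X, k):
    """Explicit eigendecomposition of the correlation matrix (independent path)."""
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    C = (Xs.T @ Xs) / (len(X) - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:k]
    return w[order], V[:, order] * np.sqrt(np.maximum(w[order], 0))


def match_sign(A, B):
    """Align per-column signs of B to A (components are sign-indeterminate)."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1
    return B * signs


# ---------------------------------------------------------------------------
# eigen-scaled PCA
# ---------------------------------------------------------------------------

def test_duplicated_variables_get_equal_loadings():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(80, 10))
    X[:, 1] = X[:, 0]
    model = EigenScaledPCA(n_components=5, svd_solver="full").fit(X)
    np.testing.assert_allclose(model.loadings_[0], model.loadings_[1], atol=1e-10)


def test_loadings_match_correlation_eigendecomposition():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(120, 60)) @ rng.normal(size=(60, 60))
    model = EigenScaledPCA(n_components=6, svd_solver="full").fit(X)
    w, L = correlation_pca_oracle(X, 6)
    np.testing.assert_allclose(model.eigenvalues_, w, rtol=1e-10)
    np.testing.assert_allclose(model.loadings_, match_sign(model.loadings_, L), atol=1e-8)


def test_rank_k_reconstruction():
    """scores @ components reproduces the rank-K truncation of the standardised matrix."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 30))
    k = 8
    model = EigenScaledPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    truncation = U[:, :k] * S[:k] @ Vt[:k]
    np.testing.assert_allclose(scores @ model.components_, truncation, atol=1e-8)


def test_full_rank_eigenvalue_sum_equals_variable_count():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 20))
    model = EigenScaledPCA(n_components=20, svd_solver="full").fit(X)
    assert model.eigenvalues_.sum() == pytest.approx(20.0, abs=1e-8)


def test_constant_columns_dropped_and_k_reduced():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 5))
    X[:, 2] = 7.0
    with pytest.warns(UserWarning, match="exceeds the matrix rank"):
        model = EigenScaledPCA(n_components=5, svd_solver="full").fit(X)
    assert list(model.dropped_) == [2]
    assert model.n_components_ == 4


def test_randomized_solver_agrees_with_full():
    rng = np.random.default_rng(5)
    latent = rng.normal(size=(150, 4)) * np.array([8.0, 5.0, 3.0, 2.0])
    X = latent @ rng.normal(size=(4, 120)) + 0.3 * rng.normal(size=(150, 120))
    full = EigenScaledPCA(n_components=4, svd_solver="full").fit(X)
    rand = EigenScaledPCA(n_components=4, svd_solver="randomized", random_state=0).fit(X)
    np.testing.assert_allclose(rand.eigenvalues_, full.eigenvalues_, rtol=1e-6)
    np.testing.assert_allclose(
        rand.loadings_, match_sign(rand.loadings_, full.loadings_), atol=1e-6
    )


def test_scree_retains_components_above_mean_eigenvalue():
    rng = np.random.default_rng(6)
    latent = rng.normal(size=(200, 2))
    X = latent @ rng.normal(size=(2, 30)) * 3 + rng.normal(size=(200, 30))
    model = EigenScaledPCA(n_components="scree", svd_solver="full").fit(X)
    assert 1 <= model.n_components_ <= 5


# ---------------------------------------------------------------------------
# direction and projections
# ---------------------------------------------------------------------------

def test_direction_aligns_with_separating_component():
    rng = np.random.default_rng(7)
    y = np.arange(100) < 50
    scores = rng.normal(size=(100, 4)) * 0.2
    scores[:, 0] += np.where(y, 3.0, -3.0)
    direction = case_control_direction(scores, y)
    assert abs(direction[0]) > 0.99
    assert direction[0] > 0  # cases positive
    assert np.linalg.norm(direction) == pytest.approx(1.0)


def test_direction_swapping_labels_flips_sign():
    rng = np.random.default_rng(8)
    y = rng.random(60) < 0.5
    scores = rng.normal(size=(60, 3))
    d1 = case_control_direction(scores, y)
    d2 = case_control_direction(scores, ~y)
    np.testing.assert_allclose(d1, -d2, atol=1e-12)


def test_direction_methods_agree_up_to_scale():
    rng = np.random.default_rng(9)
    y = rng.random(200) < 0.5
    scores = rng.normal(size=(200, 3))
    scores[:, 1] += np.where(y, 1.0, -1.0)
    d_mean = case_control_direction(scores, y, "mean_diff")
    d_corr = case_control_direction(scores, y, "dummy_corr")
    # same dominant axis, same orientation
    assert np.argmax(np.abs(d_mean)) == np.argmax(np.abs(d_corr)) == 1
    assert np.sign(d_mean[1]) == np.sign(d_corr[1])


def test_permuted_labels_have_small_direction_norm():
    rng = np.random.default_rng(10)
    y = np.arange(400) < 200
    scores = rng.normal(size=(400, 3))
    scores[:, 0] += np.where(y, 2.0, -2.0)
    raw_true = scores[y].mean(0) - scores[~y].mean(0)
    y_perm = rng.permutation(y)
    raw_perm = scores[y_perm].mean(0) - scores[~y_perm].mean(0)
    assert np.linalg.norm(raw_perm) < 0.2 * np.linalg.norm(raw_true)


def test_no_separation_raises():
    scores = np.zeros((10, 2))
    with pytest.raises(ValueError, match="separation"):
        case_control_direction(scores, np.arange(10) < 5)


def test_projection_axis_aligned_and_orthogonal_cases():
    loadings = np.array([[0.5, 0.0], [0.0, 0.7], [0.3, 0.4]])
    axis = np.array([1.0, 0.0])
    proj = projected_loadings(loadings, axis)
    assert proj[0] == pytest.approx(0.5)  # equals the PC1 scaled loading
    assert proj[1] == pytest.approx(0.0)  # variable entirely on PC2 projects to 0


def test_component_sign_flip_leaves_projections_unchanged():
    rng = np.random.default_rng(11)
    L = rng.normal(size=(20, 4))
    d = rng.normal(size=4)
    d /= np.linalg.norm(d)
    flip = np.array([1, -1, 1, -1.0])
    np.testing.assert_allclose(
        projected_loadings(L, d), projected_loadings(L * flip, d * flip), atol=1e-12
    )


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def test_kernel_matches_composed_transformers(tiny_cohort):
    """The fast permutation kernel reproduces the LBF + PCA + projection path."""
    ds = tiny_cohort
    y = np.random.default_rng(12).permutation(ds.is_case)
    kernel = _PipelineKernel(
        ds.G, x_mask=ds.x_linked, male=ds.is_male, n_categories=None,
        pseudocount=0.5, n_components=4, svd_solver="full",
    )
    L_kernel = kernel.lbf(y)
    L_ref = LBFTransformer(0.5).fit_transform(
        ds.G, y, x_mask=ds.x_linked, male=ds.is_male
    )
    np.testing.assert_allclose(L_kernel, L_ref, atol=1e-10)
    proj = kernel.projected(y)
    pca = EigenScaledPCA(n_components=4, svd_solver="full")
    scores = pca.fit_transform(L_ref)
    expected = projected_loadings(pca.loadings_full(), case_control_direction(scores, y))
    np.testing.assert_allclose(proj, expected, atol=1e-8)


def test_permutation_null_is_deterministic(tiny_cohort):
    ds = tiny_cohort
    kwargs = dict(x_mask=ds.x_linked, male=ds.is_male, n_permutations=5, seed=3)
    a = dg.permutation_null(ds.G, ds.is_case, **kwargs)
    b = dg.permutation_null(ds.G, ds.is_case, **kwargs)
    np.testing.assert_array_equal(a, b)


def test_null_is_exchangeable_with_fresh_permutations(tiny_cohort):
    """A fresh random relabelling's projections look like draws from the null.

    Note the null columns are not centred at zero: the LBF transform aligns
    every variable with its own (permuted) contrast, so projections carry a
    positive offset under any labelling.  Exchangeability shows up as the
    fresh statistic ranking uniformly within the permutation null.
    """
    ds = tiny_cohort
    null = dg.permutation_null(
        ds.G, ds.is_case, x_mask=ds.x_linked, male=ds.is_male,
        n_permutations=100, seed=4,
    )
    extra = dg.permutation_null(
        ds.G, ds.is_case, x_mask=ds.x_linked, male=ds.is_male,
        n_permutations=10, seed=99,
    )
    # mean rank of fresh draws within the null, pooled over variables
    ranks = (extra[:, None, :] > null[None, :, :]).mean(axis=1)
    assert 0.40 < ranks.mean() < 0.60


# ---------------------------------------------------------------------------
# Gaussian-mixture p-values
# ---------------------------------------------------------------------------

def test_gmm_p_half_at_null_median():
    rng = np.random.default_rng(13)
    null = rng.normal(size=(2000, 1))
    table = gmm_pvalues(np.array([np.median(null)]), null, seed=0)
    assert table["p_value"].iloc[0] == pytest.approx(0.5, abs=0.05)


def test_gmm_p_matches_normal_quantile():
    rng = np.random.default_rng(14)
    null = rng.normal(size=(5000, 1))
    table = gmm_pvalues(np.array([1.6449]), null, seed=0)
    assert table["p_value"].iloc[0] == pytest.approx(0.05, abs=0.01)


def test_gmm_p_far_tail_is_tiny():
    rng = np.random.default_rng(15)
    null = rng.normal(size=(1000, 1))
    table = gmm_pvalues(np.array([10.0 * null.std()]), null, seed=0)
    assert table["p_value"].iloc[0] < 1e-8


def test_gmm_degenerate_null():
    null = np.zeros((200, 1))
    assert gmm_pvalues(np.array([0.0]), null, seed=0)["p_value"].iloc[0] == 1.0
    tiny = gmm_pvalues(np.array([1.0]), null, seed=0)["p_value"].iloc[0]
    assert 0 < tiny < 1e-100


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def test_sidak_closed_form():
    assert dg.sidak_threshold(0.05, 1) == pytest.approx(0.05)
    assert dg.sidak_threshold(0.05, 2) == pytest.approx(1 - np.sqrt(0.95), rel=1e-12)


def test_sidak_high_precision_large_m():
    import sympy

    m = 480_785
    exact = float(1 - (1 - sympy.Rational(5, 100)) ** sympy.Rational(1, m))
    assert dg.sidak_threshold(0.05, m) == pytest.approx(exact, rel=1e-12)


def test_sidak_monotone_in_m():
    values = [dg.sidak_threshold(0.05, m) for m in (1, 10, 100, 10_000, 1_000_000)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_bh_step_up_example():
    passes = dg.bh_select(np.array([0.01, 0.02, 0.04, 0.9]), alpha=0.05)
    assert list(passes) == [True, True, False, False]


def test_bh_degenerate_and_boundary():
    assert not dg.bh_select(np.array([1.0, 1.0, 1.0]), 0.05).any()
    assert dg.bh_select(np.array([0.05]), 0.05).all()  # p == alpha*1/1 passes


# ---------------------------------------------------------------------------
# plot exports
# ---------------------------------------------------------------------------

def test_export_plots_schema(tmp_path, tiny_cohort):
    model = dg.DivergenceAnalysis(n_components=3, n_permutations=30, random_state=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(
            tiny_cohort.G, tiny_cohort.is_case, x_mask=tiny_cohort.x_linked,
            male=tiny_cohort.is_male, variants=tiny_cohort.variants,
        )
    paths = dg.export_plots(model, tiny_cohort, tmp_path)
    biplot = pd.read_csv(paths["biplot"], sep="\t")
    assert len(biplot) == tiny_cohort.n_samples + tiny_cohort.n_variants + 1
    manhattan = pd.read_csv(paths["manhattan"], sep="\t")
    # sorted by (chrom, pos)
    grouped = manhattan.groupby("chrom", sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing)
    assert grouped.all()
    # case and control mean scores separate along the first axis
    cases = biplot[(biplot["kind"] == "sample") & (biplot["group"] == "case")]["x"].mean()
    ctrls = biplot[(biplot["kind"] == "sample") & (biplot["group"] == "control")]["x"].mean()
    assert cases > ctrls
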