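"""Eigen-scaled correlation PCA of the LBF matrix and permutation significance.

The multivariate engine: columns of the LBF matrix are standardised and
decomposed by SVD; principal components are scaled by their eigenvalues, so
variable loadings are correlation-style loadings (eigenvector times the
square root of the eigenvalue).  Subjects and variables share the component
space, cases and controls define a direction in it, and each variable's
contribution to the case/control contrast is the projection of its scaled
loading onto that direction.

Significance comes from re-running the entire pipeline — model estimation,
LBF transform, PCA, direction, projection — under permuted case/control
labels, then fitting a Gaussian mixture (1-3 components, BIC-selected) to
each variable's permutation distribution and reading the observed projection
off the mixture's upper tail.  This parametric tail gives p-value resolution
far below 1/n_permutations.  Family-wise error is controlled by the Sidak
threshold at the exact number of tests; the Benjamini-Hochberg step-up flag
is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.extmath import randomized_svd
from statsmodels.stats.multitest import multipletests

from .datasets import GenotypeDataset
from .lbf import LBFTransformer, dataset_categories
from .utils import derived_int_seed, logger, seeded_rng

_P_FLOOR = float(np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# eigen-scaled PCA
# ---------------------------------------------------------------------------

class EigenScaledPCA(TransformerMixin, BaseEstimator):
    """Correlation PCA with eigenvalue-scaled variable loadings.

    Columns are standardised to zero mean / unit variance (constant columns
    are dropped and logged); the truncated SVD of the standardised matrix
    gives subject scores ``U S`` and eigenvalues ``S^2 / (n - 1)``; variable
    loadings are ``V sqrt(eigenvalue)`` so that, at full rank, loadings
    reproduce the correlations between variables and component scores.

    Parameters
    ----------
    n_components : int or "scree"
        Number of retained components; "scree" keeps components whose
        eigenvalue exceeds the mean eigenvalue.
    svd_solver : {"auto", "full", "randomized"}
        "auto" uses exact LAPACK SVD for small matrices and seeded
        randomized SVD for large ones.
    """

    def __init__(self, n_components=5, svd_solver: str = "auto", random_state: int | None = 0,
                 svd_n_iter: int = 4, svd_dtype: str | None = None):
        self.n_components = n_components
        self.svd_solver = svd_solver
        self.random_state = random_state
        self.svd_n_iter = svd_n_iter  # power iterations for the randomized solver
        self.svd_dtype = svd_dtype  # e.g. "float32" to trade precision for speed

    def _resolve_solver(self, n: int, m: int) -> str:
        if self.svd_solver != "auto":
            return self.svd_solver
        if self.n_components == "scree" or n * m <= 250_000:
            return "full"
        k = int(self.n_components)
        return "randomized" if k < min(n, m) // 2 else "full"

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None, **fit_params):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        self.kept_ = np.flatnonzero(keep)
        self.dropped_ = np.flatnonzero(~keep)
        if self.dropped_.size:
            logger.info("dropping %d constant variables before PCA", self.dropped_.size)
        self.scale_ = np.where(keep, sd, 1.0)
        Xs = (X[:, keep] - self.mean_[keep]) / sd[keep]
        m_kept = Xs.shape[1]
        rank_cap = min(n - 1, m_kept)
        solver = self._resolve_solver(n, m_kept)
        if self.n_components == "scree":
            k = rank_cap
        else:
            k = int(self.n_components)
            if k > rank_cap:
                warnings.warn(
                    f"n_components={k} exceeds the matrix rank bound {rank_cap}; reducing"
                )
                k = rank_cap
        if n - 1 < 1 or k < 1:
            raise ValueError("need at least 2 samples and 1 component")
        if solver == "full":
            U, S, Vt = linalg.svd(Xs, full_matrices=False)
            U, S, Vt = U[:, :k], S[:k], Vt[:k]
        elif solver == "randomized":
            work = Xs if self.svd_dtype is None else Xs.astype(self.svd_dtype)
            U, S, Vt = randomized_svd(
                work, n_components=k, n_oversamples=10, n_iter=self.svd_n_iter,
                random_state=self.random_state,
            )
            U, S, Vt = (np.asarray(a, dtype=float) for a in (U, S, Vt))
        else:
            raise ValueError(f"unknown svd_solver {solver!r}")
        # deterministic sign: largest-magnitude loading of each component positive
        anchor = np.argmax(np.abs(Vt), axis=1)
        signs = np.sign(Vt[np.arange(Vt.shape[0]), anchor])
        signs[signs == 0] = 1.0
        Vt = Vt * signs[:, None]
        U = U * signs[None, :]
        eigenvalues = S**2 / (n - 1)
        if self.n_components == "scree":
            # retain components above the mean eigenvalue (trace = m_kept at full rank)
            mean_eig = eigenvalues.sum() / m_kept if m_kept else 0.0
            k = max(1, int((eigenvalues > mean_eig).sum()))
            U, S, Vt, eigenvalues = U[:, :k], S[:k], Vt[:k], eigenvalues[:k]
        self.n_components_ = k
        self.eigenvalues_ = eigenvalues
        self.components_ = Vt
        self.loadings_ = Vt.T * np.sqrt(eigenvalues)[None, :]
        self.n_samples_ = n
        self.n_features_in_ = m
        scores = U * S[None, :]
        self.scores_ = scores
        return scores

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Xs = (X[:, self.kept_] - self.mean_[self.kept_]) / self.scale_[self.kept_]
        return Xs @ self.components_.T

    def loadings_full(self) -> np.ndarray:
        """Scaled loadings embedded over all input variables (dropped -> 0)."""
        out = np.zeros((self.n_features_in_, self.n_components_))
        out[self.kept_] = self.loadings_
        return out


# ---------------------------------------------------------------------------
# case/control direction and projections
# ---------------------------------------------------------------------------

def case_control_direction(
    scores: np.ndarray, y_case: np.ndarray, method: str = "mean_diff"
) -> np.ndarray:
    """Unit vector in component space along the case/control contrast.

    ``mean_diff`` uses the difference of class-mean score vectors;
    ``dummy_corr`` correlates the case dummy variable with each component's
    scores (the two coincide up to scale for standardised scores).  Oriented
    so that cases lie on the positive side.
    """
    y_case = np.asarray(y_case, dtype=bool)
    if not y_case.any() or y_case.all():
        raise ValueError("both classes must be present")
    if method == "mean_diff":
        vec = scores[y_case].mean(axis=0) - scores[~y_case].mean(axis=0)
    elif method == "dummy_corr":
        dummy = y_case.astype(float)
        dummy -= dummy.mean()
        centred = scores - scores.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vec = (dummy @ centred) / (
                np.linalg.norm(dummy) * np.linalg.norm(centred, axis=0)
            )
        vec = np.nan_to_num(vec)
    else:
        raise ValueError(f"unknown direction method {method!r}")
    nrm = np.linalg.norm(vec)
    if nrm < 1e-12:
        raise ValueError("no case/control separation: class mean scores coincide")
    return vec / nrm


def projected_loadings(loadings: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Scalar contribution of each variable: scaled loading . unit direction."""
    loadings = np.asarray(loadings)
    direction = np.asarray(direction)
    if loadings.shape[1] != direction.shape[0]:
        raise ValueError("loading and direction dimensions disagree")
    return loadings @ direction


# ---------------------------------------------------------------------------
# fast full-pipeline kernel (shared by the observed fit and permutations)
# ---------------------------------------------------------------------------

class _PipelineKernel:
    """Pre-indexed re-analysis kernel: labels in, projected loadings out.

    Precomputes per-category indicator matrices per sample stratum so each
    permutation re-estimates the class models, rebuilds the LBF matrix,
    refits the PCA and recomputes the projected loadings at matrix-multiply
    cost.  Numerically identical to composing LBFTransformer and
    EigenScaledPCA on the same inputs.
    """

    def __init__(self, X, *, x_mask, male, n_categories, pseudocount, n_components,
                 svd_solver="auto", random_state=0, svd_n_iter=4, svd_dtype=None):
        X = np.asarray(X)
        n, m = X.shape
        self.n, self.m = n, m
        self.pseudocount = pseudocount
        self.n_components = n_components
        self.svd_solver = svd_solver
        self.random_state = random_state
        self.svd_n_iter = svd_n_iter
        self.svd_dtype = svd_dtype
        if n_categories is None:
            n_categories = np.full(m, 3, dtype=int)
        kmax = max(int(np.max(n_categories)), 3)
        self.kmax = kmax
        x_mask = np.zeros(m, dtype=bool) if x_mask is None else np.asarray(x_mask, dtype=bool)
        male = np.zeros(n, dtype=bool) if male is None else np.asarray(male, dtype=bool)
        strata = [(np.ones(n, dtype=bool), np.flatnonzero(~x_mask), None)]
        if x_mask.any():
            strata.append((~male, np.flatnonzero(x_mask), None))
            strata.append((male, np.flatnonzero(x_mask), "male_x"))
        self.strata = []
        cat_support = np.arange(kmax)[:, None] < np.asarray(n_categories)[None, :]
        for rows, cols, kind in strata:
            sub = X[np.ix_(rows, cols)]
            indicators = [(sub == c).astype(np.float64) for c in range(kmax)]
            if kind == "male_x":
                support = np.zeros((kmax, cols.size), dtype=bool)
                support[0] = support[2] = True
            else:
                support = cat_support[:, cols]
            self.strata.append(
                {"rows": rows, "cols": cols, "indicators": indicators, "support": support}
            )

    def lbf(self, y_case: np.ndarray) -> np.ndarray:
        y_case = np.asarray(y_case, dtype=bool)
        L = np.zeros((self.n, self.m))
        for stratum in self.strata:
            rows, cols = stratum["rows"], stratum["cols"]
            support = stratum["support"]
            w_case = y_case[rows].astype(float)
            w_ctrl = 1.0 - w_case
            counts_case = np.stack([w_case @ ind for ind in stratum["indicators"]])
            counts_ctrl = np.stack([w_ctrl @ ind for ind in stratum["indicators"]])
            k = support.sum(axis=0)
            pc = self.pseudocount
            p_case = np.where(
                support, (counts_case + pc) / (counts_case.sum(axis=0) + k * pc), 1.0
            )
            p_ctrl = np.where(
                support, (counts_ctrl + pc) / (counts_ctrl.sum(axis=0) + k * pc), 1.0
            )
            # pooled fallback where one class never observed a variable
            empty_case = counts_case.sum(axis=0) == 0
            empty_ctrl = counts_ctrl.sum(axis=0) == 0
            if empty_case.any() or empty_ctrl.any():
                pooled_counts = counts_case + counts_ctrl
                pooled = np.where(
                    support, (pooled_counts + pc) / (pooled_counts.sum(axis=0) + k * pc), 1.0
                )
                p_case[:, empty_case] = pooled[:, empty_case]
                p_ctrl[:, empty_ctrl] = pooled[:, empty_ctrl]
            with np.errstate(divide="ignore"):
                table = np.log(p_case) - np.log(p_ctrl)
            table[~support] = 0.0
            block = np.zeros((int(rows.sum()), cols.size))
            for c, ind in enumerate(stratum["indicators"]):
                row = table[c]
                if np.any(row):
                    block += ind * row[None, :]
            L[np.ix_(rows, cols)] = block
        return L

    def projected(self, y_case: np.ndarray) -> np.ndarray:
        """Full re-analysis for one labelling; returns per-variable projections."""
        L = self.lbf(y_case)
        pca = EigenScaledPCA(
            n_components=self.n_components, svd_solver=self.svd_solver,
            random_state=self.random_state, svd_n_iter=self.svd_n_iter,
            svd_dtype=self.svd_dtype,
        )
        scores = pca.fit_transform(L)
        direction = case_control_direction(scores, y_case)
        return projected_loadings(pca.loadings_full(), direction)


def permutation_null(
    X,
    y_case,
    n_components: int = 5,
    n_permutations: int = 200,
    seed: int = 0,
    *,
    x_mask=None,
    male=None,
    n_categories=None,
    pseudocount: float = 0.5,
    svd_solver: str = "auto",
    kernel: "_PipelineKernel | None" = None,
) -> np.ndarray:
    """Null projected-loading matrix (n_permutations x n_variables).

    Each row is a full re-analysis — class models, LBF transform, PCA,
    case/control direction, projections — under one random permutation of
    the case/control labels.
    """
    if kernel is None:
        kernel = _PipelineKernel(
            X, x_mask=x_mask, male=male, n_categories=n_categories,
            pseudocount=pseudocount, n_components=n_components,
            svd_solver=svd_solver, random_state=derived_int_seed(seed, "perm-svd"),
        )
    rng = seeded_rng(seed, "permutations")
    y_case = np.asarray(y_case, dtype=bool)
    null = np.empty((n_permutations, kernel.m))
    for b in range(n_permutations):
        null[b] = kernel.projected(rng.permutation(y_case))
    return null


# ---------------------------------------------------------------------------
# Gaussian-mixture tail p-values
# ---------------------------------------------------------------------------

def _fit_best_gmm(values: np.ndarray, random_state: int, max_components: int = 3):
    best, best_bic, best_k = None, np.inf, 0
    values = values.reshape(-1, 1)
    for k in range(1, max_components + 1):
        if len(values) < 2 * k:
            break
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=1, max_iter=100,
            reg_covar=max(1e-12, 1e-6 * float(values.var())),
            random_state=random_state,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gmm.fit(values)
        except ValueError:
            continue
        bic = gmm.bic(values)
        if bic < best_bic - 1e-9:  # ties -> fewer components
            best, best_bic, best_k = gmm, bic, k
    return best, best_k


def gmm_tail_pvalue(observed: float, null_values: np.ndarray, random_state: int = 0,
                    two_sided: bool = False) -> tuple[float, int]:
    """Upper-tail mixture p-value for one variable; returns (p, n_components)."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 2 or null_values.std() == 0:
        const = null_values[0] if null_values.size else 0.0
        logger.warning("degenerate permutation null (zero variance)")
        return (1.0 if np.isclose(observed, const) else _P_FLOOR), 0
    gmm, k = _fit_best_gmm(null_values, random_state)
    if gmm is None:
        raise RuntimeError("Gaussian mixture fit failed for permutation null")
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    upper = float(weights @ norm.sf(observed, loc=means, scale=sds))
    if two_sided:
        lower = float(weights @ norm.cdf(observed, loc=means, scale=sds))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = upper
    return max(p, _P_FLOOR), k


def gmm_pvalues(
    observed: np.ndarray,
    null: np.ndarray,
    seed: int = 0,
    two_sided: bool = False,
    columns: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variable mixture tail p-values from a permutation null matrix.

    ``null`` has shape (n_permutations, n_variables); ``columns`` optionally
    restricts the computation to an index subset (others get p = NaN).
    """
    observed = np.asarray(observed, dtype=float)
    m = observed.shape[0]
    if null.shape[1] != m:
        raise ValueError("null matrix does not match the observed vector")
    if null.shape[0] < 100:
        warnings.warn("fewer than 100 permutations: tail p-values will be unstable")
    pvals = np.full(m, np.nan)
    ks = np.zeros(m, dtype=int)
    index = np.arange(m) if columns is None else np.asarray(columns)
    base = derived_int_seed(seed, "gmm")
    for j in index:
        pvals[j], ks[j] = gmm_tail_pvalue(
            observed[j], null[:, j], random_state=(base + int(j)) % (2**31),
            two_sided=two_sided,
        )
    return pd.DataFrame({"p_value": pvals, "gmm_components": ks})


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def sidak_threshold(alpha: float, m: int) -> float:
    """Per-test p-value threshold controlling FWER at ``alpha`` over ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(-np.expm1(np.log1p(-alpha) / m))


def bh_select(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up pass flags at FDR level ``alpha``."""
    pvalues = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(pvalues)
    flags = np.zeros(pvalues.shape, dtype=bool)
    if ok.any():
        flags[ok] = multipletests(pvalues[ok], alpha=alpha, method="fdr_bh")[0]
    return flags


# ---------------------------------------------------------------------------
# orchestrating estimator
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    significance: pd.DataFrame
    pca: EigenScaledPCA
    direction: np.ndarray
    null: np.ndarray
    sidak_threshold: float


class DivergenceAnalysis(BaseEstimator):
    """Case/control LBF-PCA analysis with permutation significance.

    ``fit(X, y)`` runs the observed analysis and the permutation null and
    assembles the per-variable significance table.  ``X`` holds genotype
    codes (0/1/2, -1 missing; category indices for categorical variables),
    ``y`` a case indicator (bool/int or "case"/"control" strings).

    Parameters mirror the study settings: 5 retained components, 10 000
    permutations, FWER alpha 0.05 with the Sidak correction at the exact
    number of tests, one-sided upper-tail p-values in the case-positive
    orientation.
    """

    def __init__(
        self,
        n_components: int = 5,
        n_permutations: int = 10_000,
        pseudocount: float = 0.5,
        alpha: float = 0.05,
        two_sided: bool = False,
        svd_solver: str = "auto",
        direction_method: str = "mean_diff",
        random_state: int = 0,
        pvalue_columns: np.ndarray | None = None,
        svd_n_iter: int = 4,
        svd_dtype: str | None = None,
    ):
        self.n_components = n_components
        self.n_permutations = n_permutations
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.two_sided = two_sided
        self.svd_solver = svd_solver
        self.direction_method = direction_method
        self.random_state = random_state
        self.pvalue_columns = pvalue_columns
        self.svd_n_iter = svd_n_iter
        self.svd_dtype = svd_dtype

    def fit(self, X, y, x_mask=None, male=None, n_categories=None, variants=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if y.dtype.kind in ("U", "S", "O"):
            y = y == "case"
        y = y.astype(bool)

        lbf = LBFTransformer(pseudocount=self.pseudocount)
        L = lbf.fit_transform(X, y, x_mask=x_mask, male=male, n_categories=n_categories)
        pca = EigenScaledPCA(
            n_components=self.n_components, svd_solver=self.svd_solver,
            random_state=derived_int_seed(self.random_state, "observed-svd"),
            svd_n_iter=self.svd_n_iter, svd_dtype=self.svd_dtype,
        )
        scores = pca.fit_transform(L)
        # orient components so the case-mean score is non-negative on each axis
        flip = np.sign(scores[y].mean(axis=0) - scores[~y].mean(axis=0))
        flip[flip == 0] = 1.0
        pca.components_ *= flip[:, None]
        pca.loadings_ *= flip[None, :]
        pca.scores_ = scores * flip[None, :]
        direction = case_control_direction(pca.scores_, y, method=self.direction_method)
        observed = projected_loadings(pca.loadings_full(), direction)

        kernel = _PipelineKernel(
            X, x_mask=x_mask, male=male, n_categories=n_categories,
            pseudocount=self.pseudocount, n_components=self.n_components,
            svd_solver=self.svd_solver,
            random_state=derived_int_seed(self.random_state, "perm-svd"),
            svd_n_iter=self.svd_n_iter, svd_dtype=self.svd_dtype,
        )
        null = permutation_null(
            X, y, n_permutations=self.n_permutations, seed=self.random_state, kernel=kernel
        )
        ptable = gmm_pvalues(
            observed, null, seed=self.random_state, two_sided=self.two_sided,
            columns=self.pvalue_columns,
        )
        # every variable is a test, whether or not its p-value was materialised
        threshold = sidak_threshold(self.alpha, X.shape[1])
        table = pd.DataFrame(
            {
                "variant_id": (
                    variants["variant_id"].to_numpy()
                    if variants is not None
                    else np.array([f"v{j}" for j in range(X.shape[1])])
                ),
                "chrom": variants["chrom"].to_numpy() if variants is not None else "NA",
                "pos": variants["pos"].to_numpy() if variants is not None else 0,
                "projected_loading": observed,
                "p_value": ptable["p_value"].to_numpy(),
                "gmm_components": ptable["gmm_components"].to_numpy(),
            }
        )
        table["sidak_pass"] = table["p_value"] <= threshold
        table["bh_pass"] = bh_select(table["p_value"].to_numpy(), self.alpha)
        self.lbf_ = lbf
        self.pca_ = pca
        self.direction_ = direction
        self.observed_ = observed
        self.null_ = null
        self.sidak_threshold_ = threshold
        self.significance_ = table
        self.y_ = y
        return self

    @property
    def result_(self) -> AnalysisResult:
        return AnalysisResult(
            self.significance_, self.pca_, self.direction_, self.null_, self.sidak_threshold_
        )


def analyze_dataset(dataset: GenotypeDataset, config=None, **overrides) -> DivergenceAnalysis:
    """Run the full analysis on a phenotyped dataset using ``RunConfig`` settings."""
    from .config import DEFAULT_CONFIG

    config = config or DEFAULT_CONFIG
    params = dict(
        n_components=config.n_components,
        n_permutations=config.n_permutations,
        pseudocount=config.pseudocount,
        alpha=config.fwer_alpha,
        two_sided=config.two_sided,
        random_state=config.seed,
    )
    params.update(overrides)
    model = DivergenceAnalysis(**params)
    return model.fit(
        dataset.G,
        dataset.is_case,
        x_mask=dataset.x_linked,
        male=dataset.is_male,
        n_categories=dataset_categories(dataset),
        variants=dataset.variants,
    )


# ---------------------------------------------------------------------------
# plot exports
# ---------------------------------------------------------------------------

def export_plots(
    model: DivergenceAnalysis,
    dataset: GenotypeDataset,
    out_dir,
    render: bool = False,
) -> dict:
    """Write biplot and Manhattan tables (TSV); optionally render PNGs.

    The biplot table holds subject scores, variable coordinates (first two
    scaled loadings) and the case/control dummy arrow; the Manhattan table
    holds -log10 p per variant sorted by (chrom, pos).
    """
    from pathlib import Path

    from .io import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = model.pca_.scores_
    loadings = model.pca_.loadings_full()
    rows = [
        pd.DataFrame(
            {
                "kind": "sample",
                "id": dataset.sample_ids,
                "group": dataset.samples["phenotype"].fillna("unknown"),
                "x": scores[:, 0],
                "y": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            }
        ),
        pd.DataFrame(
            {
                "kind": "variable",
                "id": dataset.variant_ids,
                "group": "variant",
                "x": loadings[:, 0],
                "y": loadings[:, 1] if loadings.shape[1] > 1 else 0.0,
            }
        ),
        pd.DataFrame(
            {
                "kind": ["dummy"],
                "id": ["case_control"],
                "group": ["direction"],
                "x": [model.direction_[0]],
                "y": [model.direction_[1] if model.direction_.shape[0] > 1 else 0.0],
            }
        ),
    ]
    biplot = pd.concat(rows, ignore_index=True)
    sig = model.significance_.copy()
    sig["neg_log10_p"] = -np.log10(sig["p_value"])
    chrom_order = {str(c): i for i, c in enumerate(
        [str(i) for i in range(1, 23)] + ["X", "HLA", "P"], start=1)}
    sig["_chrom_rank"] = sig["chrom"].astype(str).map(chrom_order).fillna(99)
    manhattan = sig.sort_values(["_chrom_rank", "pos"], kind="stable").drop(columns="_chrom_rank")
    paths = {
        "biplot": write_table(biplot, out_dir / "biplot.tsv"),
        "manhattan": write_table(manhattan, out_dir / "manhattan.tsv"),
    }
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for group, colour in (("case", "tab:red"), ("control", "tab:blue")):
            sub = biplot[(biplot["kind"] == "sample") & (biplot["group"] == group)]
            ax.scatter(sub["x"], sub["y"], s=8, alpha=0.6, label=group, color=colour)
        ax.legend()
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.savefig(out_dir / "biplot.png", dpi=120)
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.scatter(range(len(manhattan)), manhattan["neg_log10_p"], s=6)
        ax.axhline(-np.log10(model.sidak_threshold_), color="red", linestyle=":")
        ax.set_ylabel("-log10 p")
        fig.savefig(out_dir / "manhattan.png", dpi=120)
        plt.close(fig)
        paths["biplot_png"] = out_dir / "biplot.png"
        paths["manhattan_png"] = out_dir / "manhattan.png"
    return paths
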