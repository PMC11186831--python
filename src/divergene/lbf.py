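"""Genotype -> log-Bayes-factor (LBF) transformation.

Each genotype (or categorical level) is replaced by the log-likelihood ratio
of that observation under the case model versus the control model, where the
models are class-conditional category frequencies estimated from the data
with a pseudocount.  The result is a same-shape real matrix: positive cells
are evidence for case membership, negative for control, missing genotypes
contribute exactly zero evidence.

X-linked variables are modelled per sex stratum: females with three genotype
levels, hemizygous males with two levels coded {0, 2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import MISSING, GenotypeDataset


def _class_probs(counts: np.ndarray, support: np.ndarray, pseudocount: float) -> np.ndarray:
    """(count + pc) / (total + k*pc) per column over the supported categories.

    counts: (kmax, m); support: (kmax, m) bool.  Unsupported cells get 0.
    Columns with zero total are left as all-zero (caller applies a fallback).
    """
    k = support.sum(axis=0)
    totals = counts.sum(axis=0)
    denom = totals + k * pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(support, (counts + pseudocount) / denom, 0.0)
    if pseudocount == 0:
        probs[:, totals == 0] = 0.0
    else:
        probs[:, totals + k * pseudocount == 0] = 0.0
    return probs


@dataclass
class StratumModel:
    """Class-conditional category probabilities for one sample stratum."""

    columns: np.ndarray  # indices into the variable axis
    rows: np.ndarray  # boolean sample mask
    p_case: np.ndarray  # (kmax, n_cols)
    p_control: np.ndarray
    support: np.ndarray  # (kmax, n_cols) bool

    @property
    def lbf_table(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            table = np.log(self.p_case) - np.log(self.p_control)
        table[~self.support] = np.nan
        return table


@dataclass
class GenotypeModel:
    """Per-variable case/control category models, by stratum."""

    strata: list[StratumModel]
    n_variables: int
    pseudocount: float


def _count_categories(X: np.ndarray, weights: np.ndarray, kmax: int) -> np.ndarray:
    """counts[c, j] = sum of weights over samples with X[:, j] == c."""
    return np.stack([weights @ (X == c) for c in range(kmax)])


def estimate_models(
    X: np.ndarray,
    y_case: np.ndarray,
    pseudocount: float = 0.5,
    x_mask: np.ndarray | None = None,
    male: np.ndarray | None = None,
    n_categories: np.ndarray | None = None,
) -> GenotypeModel:
    """Estimate class-conditional category frequencies for every variable.

    ``X``: (n, m) integer codes with -1 missing; ``y_case``: boolean case
    indicator; ``x_mask``: X-linked column mask (requires ``male``);
    ``n_categories``: per-column level count (default 3, hemizygous male X
    columns use the two levels {0, 2}).
    """
    X = np.asarray(X)
    n, m = X.shape
    y_case = np.asarray(y_case, dtype=bool)
    if y_case.shape != (n,):
        raise ValueError("labels must align with samples")
    if not y_case.any() or y_case.all():
        raise ValueError("both phenotype classes must be non-empty")
    if n_categories is None:
        n_categories = np.full(m, 3, dtype=int)
    else:
        n_categories = np.asarray(n_categories, dtype=int)
    kmax = max(int(n_categories.max()), 3)
    if x_mask is None:
        x_mask = np.zeros(m, dtype=bool)
    if x_mask.any() and male is None:
        raise ValueError("X-linked columns require a per-sample male mask")
    male = np.zeros(n, dtype=bool) if male is None else np.asarray(male, dtype=bool)

    cat_support = np.arange(kmax)[:, None] < n_categories[None, :]
    strata: list[StratumModel] = []

    def add_stratum(rows: np.ndarray, cols: np.ndarray, support: np.ndarray) -> None:
        if cols.size == 0:
            return
        sub = X[np.ix_(rows, cols)]
        w_case = y_case[rows].astype(float)
        counts_case = _count_categories(sub, w_case, kmax)
        counts_ctrl = _count_categories(sub, 1.0 - w_case, kmax)
        p_case = _class_probs(counts_case, support, pseudocount)
        p_ctrl = _class_probs(counts_ctrl, support, pseudocount)
        # pooled fallback where one class never observed the variable
        empty_case = counts_case.sum(axis=0) == 0
        empty_ctrl = counts_ctrl.sum(axis=0) == 0
        if empty_case.any() or empty_ctrl.any():
            warnings.warn(
                "class with zero observations for some variables; "
                "falling back to the pooled distribution",
                stacklevel=3,
            )
            pooled = _class_probs(counts_case + counts_ctrl, support, pseudocount)
            p_case[:, empty_case] = pooled[:, empty_case]
            p_ctrl[:, empty_ctrl] = pooled[:, empty_ctrl]
        strata.append(StratumModel(cols, rows, p_case, p_ctrl, support))

    auto_cols = np.flatnonzero(~x_mask)
    x_cols = np.flatnonzero(x_mask)
    add_stratum(np.ones(n, dtype=bool), auto_cols, cat_support[:, auto_cols])
    if x_cols.size:
        add_stratum(~male, x_cols, cat_support[:, x_cols])
        male_support = np.zeros((kmax, x_cols.size), dtype=bool)
        male_support[0] = True
        male_support[2] = True
        add_stratum(male, x_cols, male_support)
    return GenotypeModel(strata=strata, n_variables=m, pseudocount=pseudocount)


def lbf_transform(X: np.ndarray, model: GenotypeModel) -> np.ndarray:
    """Replace each genotype by its LBF under ``model``; missing -> 0."""
    X = np.asarray(X)
    n, m = X.shape
    if m != model.n_variables:
        raise ValueError("model does not cover this variable set")
    out = np.zeros((n, m), dtype=float)
    for stratum in model.strata:
        sub = X[np.ix_(stratum.rows, stratum.columns)]
        table = stratum.lbf_table  # (kmax, n_cols)
        observed = sub != MISSING
        codes = np.where(observed, sub, 0)
        if int(codes.max(initial=0)) >= table.shape[0]:
            raise RuntimeError("genotype category absent from model")
        values = table[codes, np.arange(stratum.columns.size)[None, :]]
        if np.isnan(values[observed]).any():
            raise RuntimeError("genotype category absent from model")
        block = np.where(observed, values, 0.0)
        out[np.ix_(stratum.rows, stratum.columns)] = block
    return out


class LBFTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer from genotype codes to LBFs.

    Parameters
    ----------
    pseudocount : float, default 0.5
        Jeffreys-style smoothing added to every category count; guarantees
        finite LBFs for categories unseen in one class.
    """

    def __init__(self, pseudocount: float = 0.5):
        self.pseudocount = pseudocount

    def fit(self, X, y, x_mask=None, male=None, n_categories=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if y.dtype.kind in ("U", "S", "O"):
            y = y == "case"
        self.model_ = estimate_models(
            X, y.astype(bool), self.pseudocount,
            x_mask=x_mask, male=male, n_categories=n_categories,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return lbf_transform(np.asarray(X), self.model_)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def dataset_categories(dataset: GenotypeDataset) -> np.ndarray:
    """Per-variable level counts: 3 for SNPs, observed max + 1 for categoricals."""
    n_categories = np.full(dataset.n_variants, 3, dtype=int)
    cat = dataset.variants["is_categorical"].to_numpy()
    if cat.any():
        observed_max = np.max(
            np.where(dataset.G[:, cat] == MISSING, 0, dataset.G[:, cat]), axis=0
        )
        n_categories[cat] = np.maximum(observed_max + 1, 2)
    return n_categories


def lbf_matrix(dataset: GenotypeDataset, pseudocount: float = 0.5) -> np.ndarray:
    """Convenience: LBF matrix of a phenotyped dataset (X- and category-aware)."""
    transformer = LBFTransformer(pseudocount=pseudocount)
    return transformer.fit_transform(
        dataset.G,
        dataset.is_case,
        x_mask=dataset.x_linked,
        male=dataset.is_male,
        n_categories=dataset_categories(dataset),
    )
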