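"""Genetic-ancestry co-analysis, homogeneous-subject selection, sex balancing.

Study subjects are scored in an LBF-PCA space built from labelled reference
panels (one reference population contrasted against the others); the study
subjects themselves are passive — they are transformed with models estimated
on the panels only, so they cannot distort the contrast.  A k-means centre
on the reference cluster plus its covariance defines a Mahalanobis ellipse;
subjects within the chi-square (1 - alpha) quantile are kept as ancestrally
homogeneous.  Finally the cohort is sex-balanced to a case/control sex odds
ratio of 1 by subsampling one stratum of the more sex-imbalanced class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .datasets import MISSING, GenotypeDataset, concat_samples
from .lbf import LBFTransformer
from .analysis import EigenScaledPCA
from .utils import derived_int_seed, logger, seeded_rng


# ---------------------------------------------------------------------------
# co-analysis
# ---------------------------------------------------------------------------

def _shared_variant_ids(datasets: list[GenotypeDataset]) -> list[str]:
    shared = set(datasets[0].variant_ids)
    for d in datasets[1:]:
        shared &= set(d.variant_ids)
    # keep the first dataset's ordering
    return [v for v in datasets[0].variant_ids if v in shared]


def coanalyze(
    reference_panels: dict[str, GenotypeDataset],
    contrast_panels: dict[str, GenotypeDataset],
    unknowns: GenotypeDataset,
    n_components: int = 5,
    pseudocount: float = 0.5,
    missing_max: float = 0.05,
    random_state: int = 0,
) -> pd.DataFrame:
    """Score reference, contrast and unknown subjects in one component space.

    LBF models contrast the reference population(s) against the contrast
    population(s); the PCA is fitted on the labelled panels and unknown
    subjects are projected as supplementary points.  Variants must be shared
    by every dataset, non-monomorphic and under the total-missingness cap.

    Returns a frame with sample_id, cohort, role (reference/contrast/unknown)
    and score columns PC1..PCk.
    """
    labelled = list(reference_panels.values()) + list(contrast_panels.values())
    everything = labelled + [unknowns]
    shared = _shared_variant_ids(everything)
    if len(shared) == 0:
        raise ValueError("no variants shared across all datasets")
    if len(shared) < 1000:
        logger.warning("only %d shared variants for ancestry co-analysis", len(shared))
    aligned = [d.select_variants(shared) for d in everything]
    stacked_G = np.vstack([d.G for d in aligned])
    observed = stacked_G != MISSING
    polymorphic = np.array(
        [np.unique(col[obs]).size > 1 for col, obs in zip(stacked_G.T, observed.T)]
    )
    low_missing = (~observed).mean(axis=0) < missing_max
    usable = polymorphic & low_missing
    aligned = [d.take_variants(usable) for d in aligned]

    n_labelled = len(labelled)
    roles, cohorts = [], []
    for label, panel in reference_panels.items():
        roles += ["reference"] * panel.n_samples
        cohorts += [label] * panel.n_samples
    for label, panel in contrast_panels.items():
        roles += ["contrast"] * panel.n_samples
        cohorts += [label] * panel.n_samples
    roles += ["unknown"] * unknowns.n_samples
    cohorts += ["unknown"] * unknowns.n_samples

    labelled_stack = concat_samples(aligned[:n_labelled])
    y_reference = np.array([r == "reference" for r in roles[: labelled_stack.n_samples]])
    x_mask = labelled_stack.x_linked
    male_labelled = labelled_stack.is_male
    lbf = LBFTransformer(pseudocount=pseudocount)
    L_labelled = lbf.fit_transform(
        labelled_stack.G, y_reference, x_mask=x_mask, male=male_labelled
    )
    pca = EigenScaledPCA(
        n_components=n_components, svd_solver="auto",
        random_state=derived_int_seed(random_state, "ancestry-svd"),
    )
    scores_labelled = pca.fit_transform(L_labelled)

    unknown_aligned = aligned[-1]
    # unknowns are passive: same models, same standardisation, same components
    L_unknown = _transform_with_sex(lbf, unknown_aligned)
    scores_unknown = pca.transform(L_unknown)

    sample_ids = np.concatenate([labelled_stack.sample_ids, unknown_aligned.sample_ids])
    scores = np.vstack([scores_labelled, scores_unknown])
    out = pd.DataFrame(
        {"sample_id": sample_ids, "cohort": cohorts, "role": roles}
    )
    for k in range(scores.shape[1]):
        out[f"PC{k + 1}"] = scores[:, k]
    return out


def _transform_with_sex(lbf: LBFTransformer, dataset: GenotypeDataset) -> np.ndarray:
    """Apply a fitted LBF model to a dataset whose sex layout differs.

    The fitted model's strata row masks refer to the training samples, so a
    fresh model object is assembled with this dataset's female/male rows but
    the training probabilities.
    """
    from .lbf import GenotypeModel, StratumModel, lbf_transform

    male = dataset.is_male
    n = dataset.n_samples
    strata = []
    for stratum in lbf.model_.strata:
        cols_are_x = dataset.x_linked[stratum.columns].any()
        if not cols_are_x:
            rows = np.ones(n, dtype=bool)
        elif stratum.support[1].any():  # female stratum supports heterozygotes
            rows = ~male
        else:
            rows = male
        strata.append(
            StratumModel(stratum.columns, rows, stratum.p_case, stratum.p_control, stratum.support)
        )
    model = GenotypeModel(strata, lbf.model_.n_variables, lbf.model_.pseudocount)
    return lbf_transform(dataset.G, model)


# ---------------------------------------------------------------------------
# Mahalanobis ellipse selection
# ---------------------------------------------------------------------------

@dataclass
class AncestrySelection:
    kept: list[str]
    excluded: list[str]
    centre: np.ndarray
    covariance: np.ndarray
    alpha: float
    threshold: float
    mahalanobis2: pd.Series = field(repr=False, default=None)


class MahalanobisAncestrySelector(BaseEstimator):
    """Keep subjects inside the reference cluster's chi-square ellipse.

    Fit on reference-subject scores: k-means locates the cluster centre
    (largest cluster when ``n_clusters`` > 1) and the member covariance
    defines the metric.  A subject is kept iff its squared Mahalanobis
    distance is within the chi-square quantile ``1 - alpha`` (df = number of
    score dimensions); ``keep_tail=True`` applies the complementary reading
    (quantile ``alpha``).
    """

    def __init__(self, alpha: float = 0.2, n_clusters: int = 1, keep_tail: bool = False,
                 random_state: int = 0):
        self.alpha = alpha
        self.n_clusters = n_clusters
        self.keep_tail = keep_tail
        self.random_state = random_state

    def fit(self, reference_scores: np.ndarray, y=None):
        S = np.asarray(reference_scores, dtype=float)
        if S.ndim != 2:
            raise ValueError("scores must be 2-D (subjects x components)")
        if len(S) < 10 * max(1, self.n_clusters):
            raise ValueError("need >= 10 reference subjects per cluster")
        km = KMeans(
            n_clusters=self.n_clusters, n_init=10,
            random_state=derived_int_seed(self.random_state, "ancestry-kmeans"),
        ).fit(S)
        biggest = np.argmax(np.bincount(km.labels_))
        members = S[km.labels_ == biggest]
        self.centre_ = km.cluster_centers_[biggest]
        cov = np.cov(members, rowvar=False)
        cov = np.atleast_2d(cov)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or logdet < np.log(1e-300):
            logger.warning("singular reference covariance; applying ridge regularisation")
            cov = cov + 1e-6 * np.trace(cov) * np.eye(cov.shape[0])
        self.covariance_ = cov
        self.precision_ = np.linalg.inv(cov)
        df = S.shape[1]
        quantile = self.alpha if self.keep_tail else 1.0 - self.alpha
        self.threshold_ = float(chi2.ppf(quantile, df=df))
        return self

    def mahalanobis2(self, scores: np.ndarray) -> np.ndarray:
        diff = np.asarray(scores, dtype=float) - self.centre_
        return np.einsum("ij,jk,ik->i", diff, self.precision_, diff)

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Boolean kept-mask for each subject."""
        return self.mahalanobis2(scores) <= self.threshold_


def select_homogeneous(
    scores: pd.DataFrame,
    reference_label: str,
    alpha: float = 0.2,
    k_clusters: int = 1,
    apply_roles: tuple[str, ...] = ("unknown",),
    keep_tail: bool = False,
    random_state: int = 0,
) -> AncestrySelection:
    """Ellipse selection on a co-analysis score frame (see :func:`coanalyze`).

    The ellipse is fitted on subjects of ``reference_label``; kept/excluded
    lists cover subjects whose role is in ``apply_roles``.
    """
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    ref = scores.loc[scores["cohort"] == reference_label, pc_cols].to_numpy()
    selector = MahalanobisAncestrySelector(
        alpha=alpha, n_clusters=k_clusters, keep_tail=keep_tail, random_state=random_state
    ).fit(ref)
    subjects = scores[scores["role"].isin(apply_roles)]
    d2 = selector.mahalanobis2(subjects[pc_cols].to_numpy())
    kept_mask = d2 <= selector.threshold_
    return AncestrySelection(
        kept=list(subjects.loc[kept_mask, "sample_id"]),
        excluded=list(subjects.loc[~kept_mask, "sample_id"]),
        centre=selector.centre_,
        covariance=selector.covariance_,
        alpha=alpha,
        threshold=selector.threshold_,
        mahalanobis2=pd.Series(d2, index=subjects["sample_id"].to_numpy()),
    )


# ---------------------------------------------------------------------------
# sex balancing
# ---------------------------------------------------------------------------

def balance_sex(samples: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample one class until the case/control sex odds ratio is 1.

    Only the class with the larger sex imbalance (|log male:female|) is
    reduced, and within it only the over-represented sex stratum, to the
    nearest achievable integer composition.  Deterministic under ``seed``.
    """
    counts = {
        (phe, sex): int(((samples["phenotype"] == phe) & (samples["sex_reported"] == sex)).sum())
        for phe in ("case", "control")
        for sex in ("male", "female")
    }
    for key, value in counts.items():
        if value == 0:
            raise ValueError(f"sex balancing requires both sexes in both classes; {key} is empty")
    if counts[("case", "male")] * counts[("control", "female")] == counts[
        ("case", "female")
    ] * counts[("control", "male")]:
        return samples.copy()

    imbalance = {
        phe: abs(np.log(counts[(phe, "male")] / counts[(phe, "female")]))
        for phe in ("case", "control")
    }
    reduce_phe = "case" if imbalance["case"] >= imbalance["control"] else "control"
    other = "control" if reduce_phe == "case" else "case"
    r_other = counts[(other, "male")] / counts[(other, "female")]
    m, f = counts[(reduce_phe, "male")], counts[(reduce_phe, "female")]
    if m / f > r_other:
        target = ("male", max(1, round(f * r_other)))
    else:
        target = ("female", max(1, round(m / r_other)))
    sex_to_cut, n_keep = target
    stratum = samples[(samples["phenotype"] == reduce_phe) & (samples["sex_reported"] == sex_to_cut)]
    if n_keep >= len(stratum):
        logger.warning("sex odds ratio of 1 not exactly achievable; keeping best composition")
        return samples.copy()
    rng = seeded_rng(seed, "sex-balance")
    keep_ids = set(rng.choice(stratum["sample_id"].to_numpy(), size=n_keep, replace=False))
    drop = samples["sample_id"].isin(set(stratum["sample_id"]) - keep_ids)
    return samples[~drop].reset_index(drop=True)
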