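"""Univariate sample/variant quality control and the relatedness scan.

Filters follow array-QC convention for a case/control study: sex inference
from X-chromosome heterozygosity checked against the reported label, removal
of samples with > 5% missing genotypes, removal of one member of each highly
identical sample pair, and removal of variants that are monomorphic, have
> 5% missing values, or depart from Hardy-Weinberg equilibrium in controls
(exact test, p < 1e-8).  No minor-allele-frequency floor is applied outside
the relatedness scan: the downstream LBF analysis keeps rare variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import DEFAULT_CONFIG, RunConfig
from .datasets import MISSING, GenotypeDataset
from .utils import logger


@dataclass
class QCReport:
    """Auditable record of everything QC removed and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def sample_counts(self) -> dict[str, int]:
        return self._counts(self.removed_samples)

    @property
    def variant_counts(self) -> dict[str, int]:
        return self._counts(self.removed_variants)

    @staticmethod
    def _counts(rows) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in rows:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def samples_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_samples, columns=["sample_id", "reason"])

    def variants_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_variants, columns=["variant_id", "reason"])

    def summary(self) -> dict:
        return {
            "removed_samples": self.sample_counts,
            "removed_variants": self.variant_counts,
            "thresholds": self.thresholds,
        }


# ---------------------------------------------------------------------------
# sex inference
# ---------------------------------------------------------------------------

def infer_sex(
    dataset: GenotypeDataset,
    het_male_max: float = 0.02,
    het_female_min: float = 0.20,
    min_x_variants: int = 20,
) -> pd.DataFrame:
    """Infer sex from X-chromosome heterozygosity and flag mismatches.

    Returns a frame with per-sample X heterozygosity rate, inferred sex
    (male below ``het_male_max``, female above ``het_female_min``, else
    unknown) and a mismatch flag (inferred known and != reported).
    """
    x_cols = dataset.x_linked
    if int(x_cols.sum()) == 0:
        raise ValueError("sex inference requires X-linked variants; none present")
    if int(x_cols.sum()) < min_x_variants:
        raise ValueError(
            f"sex inference requires >= {min_x_variants} X-linked variants, "
            f"found {int(x_cols.sum())}"
        )
    GX = dataset.G[:, x_cols]
    observed = GX != MISSING
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(n_obs > 0, (GX == 1).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    inferred = np.where(
        het_rate < het_male_max, "male", np.where(het_rate > het_female_min, "female", "unknown")
    )
    inferred = np.where(np.isnan(het_rate), "unknown", inferred)
    reported = dataset.samples["sex_reported"].to_numpy()
    mismatch = (inferred != "unknown") & (inferred != reported)
    return pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "x_het_rate": het_rate,
            "sex_inferred": inferred,
            "sex_reported": reported,
            "mismatch": mismatch,
        }
    )


# ---------------------------------------------------------------------------
# sample missingness
# ---------------------------------------------------------------------------

def filter_sample_missingness(
    dataset: GenotypeDataset, max_rate: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample ids into (kept, removed) by missing rate strictly above ``max_rate``."""
    rates = dataset.sample_missing_rate()
    removed = rates > max_rate
    return dataset.sample_ids[~removed], dataset.sample_ids[removed]


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def relatedness_scan(
    dataset: GenotypeDataset,
    maf_min: float = 0.48,
    n_snps: int | None = None,
    identity_min: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise genotype-identity fractions over high-MAF SNPs.

    Uses up to ``n_snps`` highly variable autosomal SNPs (MAF strictly above
    ``maf_min``); the identity fraction of a pair is the share of co-observed
    selected variants with equal genotype codes.  Pairs above ``identity_min``
    are flagged and the higher-missingness member of each is marked for
    removal (ties break to the later sample).

    Returns (pairs, flagged) where ``pairs`` lists every pair's identity
    fraction and ``flagged`` adds the member chosen for removal.
    """
    snp = ~dataset.variants["is_categorical"].to_numpy() & ~dataset.x_linked
    G = dataset.G
    observed = (G != MISSING) & snp[None, :]
    alt = np.where(G == MISSING, 0, G)
    with np.errstate(invalid="ignore"):
        freq = alt.sum(axis=0, where=observed) / (2.0 * np.maximum(observed.sum(axis=0), 1))
    maf = np.minimum(freq, 1 - freq)
    eligible = snp & (maf > maf_min) & (observed.sum(axis=0) > 0)
    n_eligible = int(eligible.sum())
    if n_eligible < 100:
        raise ValueError(
            f"relatedness scan needs >= 100 variants with MAF > {maf_min}, found {n_eligible}"
        )
    order = np.flatnonzero(eligible)
    if n_snps is not None and n_eligible > n_snps:
        order = order[np.argsort(-maf[order], kind="stable")][:n_snps]
    elif n_snps is not None and n_eligible < n_snps:
        logger.warning(
            "only %d variants pass MAF > %.2f (requested %d); using all", n_eligible, maf_min, n_snps
        )
    sel = np.sort(order)

    Gs = G[:, sel]
    obs = Gs != MISSING
    n = dataset.n_samples
    # identical co-observed genotypes via per-category co-occurrence products
    same = np.zeros((n, n))
    for code in (0, 1, 2):
        ind = ((Gs == code)).astype(np.float32)
        same += ind @ ind.T
    co_obs = obs.astype(np.float32) @ obs.astype(np.float32).T
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(co_obs[iu] > 0, same[iu] / co_obs[iu], np.nan)
    ids = dataset.sample_ids
    pairs = pd.DataFrame(
        {
            "sample_a": ids[iu[0]],
            "sample_b": ids[iu[1]],
            "n_co_observed": co_obs[iu].astype(int),
            "identity": identity,
        }
    )
    flagged = pairs[pairs["identity"] > identity_min].copy()
    miss = dict(zip(ids, dataset.sample_missing_rate()))
    flagged["remove"] = [
        a if miss[a] > miss[b] else b for a, b in zip(flagged["sample_a"], flagged["sample_b"])
    ]
    return pairs, flagged


def expected_unrelated_identity(maf: float) -> float:
    """Closed-form identity fraction for an unrelated pair under HWE at ``maf``."""
    p, q = 1 - maf, maf
    freqs = np.array([p * p, 2 * p * q, q * q])
    return float((freqs**2).sum())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value, conditional on allele counts.

    Sums the probabilities of all heterozygote counts (with the observed
    allele counts) that are no more probable than the observed count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        logger.warning("HWE test on all-zero counts is undefined; returning 1")
        return 1.0
    n_a = n_Aa + 2 * n_aa  # minor-allele count conditioned on
    n_a = min(n_a, 2 * n - n_a)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log P(het = h | allele counts) up to a shared constant
    rare = min(n_a, 2 * n - n_a)
    n_common_hom = (2 * n - rare - hets) // 2
    n_rare_hom = (rare - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_common_hom + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed_index = np.flatnonzero(hets == n_Aa)
    if observed_index.size == 0:  # parity mismatch cannot happen with valid counts
        raise RuntimeError("observed heterozygote count inconsistent with allele counts")
    p_obs = probs[observed_index[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------

def variant_filter_flags(dataset: GenotypeDataset, config: RunConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-variant flags for the three univariate exclusion rules.

    Monomorphic in the whole population; missing rate strictly above the cap;
    HWE exact p below the floor in controls (females only for X-linked
    variants; categorical variables are exempt from HWE).
    """
    G = dataset.G
    observed = G != MISSING
    n_levels = np.array(
        [len(np.unique(G[observed[:, j], j])) for j in range(dataset.n_variants)]
    )
    monomorphic = n_levels <= 1
    missing = dataset.variant_missing_rate() > config.variant_missing_max

    is_control = dataset.phenotype_mask("control")
    female = ~dataset.is_male
    x_linked = dataset.x_linked
    categorical = dataset.variants["is_categorical"].to_numpy()
    hwe_p = np.ones(dataset.n_variants)
    for j in range(dataset.n_variants):
        if categorical[j]:
            continue
        rows = is_control & (female if x_linked[j] else True)
        col = G[rows, j]
        col = col[col != MISSING]
        counts = [int((col == c).sum()) for c in (0, 1, 2)]
        if sum(counts) == 0:
            continue
        hwe_p[j] = hwe_exact_test(*counts)
    hwe_fail = hwe_p < config.hwe_p_min
    return pd.DataFrame(
        {
            "variant_id": dataset.variant_ids,
            "monomorphic": monomorphic,
            "missingness": missing,
            "hwe": hwe_fail,
            "hwe_p": hwe_p,
        }
    )


def filter_variants(
    dataset: GenotypeDataset, config: RunConfig = DEFAULT_CONFIG
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the three variant rules; a variant may be flagged under several
    reasons but is removed once."""
    flags = variant_filter_flags(dataset, config)
    report = QCReport(
        thresholds={
            "variant_missing_max": config.variant_missing_max,
            "hwe_p_min": config.hwe_p_min,
        }
    )
    for reason in ("monomorphic", "missingness", "hwe"):
        for vid in flags.loc[flags[reason], "variant_id"]:
            report.removed_variants.append((vid, reason))
    drop = (flags[["monomorphic", "missingness", "hwe"]].any(axis=1)).to_numpy()
    return dataset.take_variants(~drop), report


# ---------------------------------------------------------------------------
# full sample + variant QC
# ---------------------------------------------------------------------------

def run_qc(
    dataset: GenotypeDataset, config: RunConfig = DEFAULT_CONFIG
) -> tuple[GenotypeDataset, QCReport]:
    """Sample QC (sex, missingness, relatedness) then variant QC.

    Returns the filtered dataset and a combined report.  Idempotent: QC on a
    QC'd dataset removes nothing.
    """
    report = QCReport(
        thresholds={
            "sample_missing_max": config.sample_missing_max,
            "variant_missing_max": config.variant_missing_max,
            "hwe_p_min": config.hwe_p_min,
            "relatedness_maf_min": config.relatedness_maf_min,
            "relatedness_identity_min": config.relatedness_identity_min,
        }
    )
    removed: set[str] = set()

    if dataset.x_linked.sum() >= 20:
        sex = infer_sex(dataset, config.sex_het_male_max, config.sex_het_female_min)
        for sid in sex.loc[sex["mismatch"], "sample_id"]:
            report.removed_samples.append((sid, "sex_mismatch"))
            removed.add(sid)
    else:
        logger.warning("fewer than 20 X-linked variants; skipping the sex check")

    _, miss_removed = filter_sample_missingness(dataset, config.sample_missing_max)
    for sid in miss_removed:
        report.removed_samples.append((sid, "missingness"))
        removed.add(sid)

    try:
        _, flagged = relatedness_scan(
            dataset,
            maf_min=config.relatedness_maf_min,
            n_snps=config.relatedness_n_snps,
            identity_min=config.relatedness_identity_min,
        )
        for sid in flagged["remove"]:
            if sid not in removed:
                report.removed_samples.append((sid, "related"))
                removed.add(sid)
    except ValueError as exc:
        logger.warning("relatedness scan skipped: %s", exc)

    kept = ~np.isin(dataset.sample_ids, list(removed))
    filtered = dataset.take_samples(kept)
    filtered, variant_report = filter_variants(filtered, config)
    report.removed_variants = variant_report.removed_variants
    return filtered, report
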