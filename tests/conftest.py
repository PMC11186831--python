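import numpy as np
import pytest

import divergene as dg


@pytest.fixture(scope="session")
def tiny_cohort() -> dg.GenotypeDataset:
    """Small clean cohort used across modules (no planted pathologies)."""
    spec = dg.SimSpec(
        n_case=120, n_control=120, n_variants=150, n_x_variants=40,
        missing_rate=0.01, seed=42,
    )
    return dg.simulate_cohort(spec)


@pytest.fixture(scope="session")
def qc_cohort() -> dg.GenotypeDataset:
    """Cohort with every QC pathology planted at known counts."""
    spec = dg.SimSpec(
        n_case=400, n_control=400, n_variants=2400, n_x_variants=60,
        maf_range=(0.2, 0.5),
        missing_rate=0.005,
        n_monomorphic=50, n_high_missing_variants=30, n_hwe_violators=10,
        n_sex_mismatches=19, n_related_pairs=5, n_high_missing_samples=2,
        seed=7,
    )
    return dg.simulate_cohort(spec)


def hwe_exact_brute(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Brute-force enumeration oracle for the exact HWE test.

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes each configuration's conditional probability from
    binomial coefficients with exact integer arithmetic, and sums those no
    more probable than the observed configuration.
    """
    from fractions import Fraction
    from math import comb

    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    na = min(n_Aa + 2 * n_aa, 2 * n - (n_Aa + 2 * n_aa))
    weights = {}
    for h in range(na % 2, na + 1, 2):
        rare_hom = (na - h) // 2
        common_hom = n - h - rare_hom
        # multinomial count x 2^h phase factor, conditional on allele counts
        weights[h] = Fraction(2**h * comb(n, h) * comb(n - h, rare_hom), 1)
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)
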