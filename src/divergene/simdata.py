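"""Synthetic case/control cohorts, reference panels and toy evidence tables.

The generator emulates the structure of an SNP-array case/control study:
autosomal SNP genotypes in Hardy-Weinberg proportions at per-variant minor
allele frequencies, X-linked variants with sex-dependent coding, planted
risk loci under a multiplicative allelic odds ratio, and the data pathologies
univariate QC must catch — monomorphic variants, high-missingness variants
and samples, HWE-violating variants, related sample pairs, sex-label
mismatches and ancestry outliers.  What it does not emulate: linkage
disequilibrium between distinct variants (columns are independent unless
explicitly duplicated), genotyping-batch effects, and realistic allele
frequency spectra.

Every planted feature is recorded in a :class:`CohortTruth` attached to the
returned dataset, so tests can assert exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset, make_sample_frame, make_variant_frame
from .utils import seeded_rng


@dataclass
class SimSpec:
    """Study-design parameters for one simulated cohort."""

    n_case: int = 500
    n_control: int = 500
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    risk_loci: list[tuple[int, float]] = field(default_factory=list)  # (variant idx, allelic OR)
    risk_maf: float | None = None  # fix the MAF at risk loci (else drawn from maf_range)
    missing_rate: float = 0.01
    n_monomorphic: int = 0
    n_hwe_violators: int = 0
    n_related_pairs: int = 0
    n_sex_mismatches: int = 0
    n_outlier_ancestry: int = 0
    sex_case_fraction_female: float = 0.5
    sex_control_fraction_female: float = 0.5
    fst_outlier: float = 0.1
    n_x_variants: int = 0
    n_high_missing_variants: int = 0
    high_missing_rate: float = 0.10
    n_high_missing_samples: int = 0
    seed: int = 0

    def validate(self) -> None:
        n_samples = self.n_case + self.n_control
        n_autosomal = self.n_variants - self.n_x_variants
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if any(oratio <= 0 for _, oratio in self.risk_loci):
            raise ValueError("allelic odds ratios must be > 0")
        if any(not 0 <= idx < n_autosomal for idx, _ in self.risk_loci):
            raise ValueError("risk locus index outside the autosomal variant range")
        planted_variants = (
            self.n_monomorphic + self.n_hwe_violators + self.n_high_missing_variants
            + len(self.risk_loci)
        )
        if planted_variants > n_autosomal:
            raise ValueError("planted variant counts exceed the number of autosomal variants")
        if 2 * self.n_related_pairs + self.n_outlier_ancestry > self.n_control:
            raise ValueError("planted related/outlier samples exceed the control count")
        if self.n_sex_mismatches + self.n_high_missing_samples > n_samples:
            raise ValueError("planted sample counts exceed the cohort size")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_x_variants and self.n_x_variants < 20:
            raise ValueError("use at least 20 X-linked variants so sex can be inferred")


@dataclass
class CohortTruth:
    """Indices/ids of every planted feature, for test assertions."""

    risk_loci: list[tuple[int, float]]
    monomorphic: np.ndarray
    hwe_violators: np.ndarray
    high_missing_variants: np.ndarray
    related_pairs: list[tuple[int, int]]
    sex_mismatches: np.ndarray
    outlier_ancestry: np.ndarray
    high_missing_samples: np.ndarray
    maf: np.ndarray


def _hwe_genotypes(rng, p, n) -> np.ndarray:
    """Genotypes (alt dosage) in HWE at alt frequency p; p may be scalar or per-variant."""
    return (rng.random((n, np.size(p))) < p).astype(np.int8) + (
        rng.random((n, np.size(p))) < p
    ).astype(np.int8)


def case_allele_frequency(p: float, odds_ratio: float) -> float:
    """Case alt-allele frequency under a multiplicative allelic odds ratio."""
    return odds_ratio * p / (1 - p + odds_ratio * p)


def balding_nichols_frequencies(rng, base: np.ndarray, fst: float) -> np.ndarray:
    """Population allele frequencies drawn around ``base`` with divergence ``fst``."""
    if fst == 0:
        return base.copy()
    a = base * (1 - fst) / fst
    b = (1 - base) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def simulate_cohort(spec: SimSpec) -> GenotypeDataset:
    """Generate one case/control cohort with the planted structure in ``spec``."""
    spec.validate()
    n_samples = spec.n_case + spec.n_control
    n_auto = spec.n_variants - spec.n_x_variants
    rng = seeded_rng(spec.seed, "cohort")

    maf = rng.uniform(*spec.maf_range, size=spec.n_variants)
    if spec.risk_maf is not None:
        for idx, _ in spec.risk_loci:
            maf[idx] = spec.risk_maf
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[: spec.n_case] = True

    # true sex, then recorded sex with planted mismatches
    sex_rng = seeded_rng(spec.seed, "cohort", "sex")
    true_female = np.empty(n_samples, dtype=bool)
    true_female[is_case] = sex_rng.random(spec.n_case) < spec.sex_case_fraction_female
    true_female[~is_case] = sex_rng.random(spec.n_control) < spec.sex_control_fraction_female

    # autosomal genotypes: HWE at maf, with a case-frequency tilt at risk loci
    p_control = np.tile(maf[:n_auto], (n_samples, 1))
    p_case_row = maf[:n_auto].copy()
    for idx, oratio in spec.risk_loci:
        p_case_row[idx] = case_allele_frequency(maf[idx], oratio)
    p = np.where(is_case[:, None], p_case_row[None, :], p_control)
    G_auto = (rng.random(p.shape) < p).astype(np.int8) + (rng.random(p.shape) < p).astype(np.int8)

    # reserve disjoint index blocks for planted variant pathologies
    risk_idx = {idx for idx, _ in spec.risk_loci}
    free = [j for j in range(n_auto) if j not in risk_idx]
    mono_idx = np.array(free[: spec.n_monomorphic], dtype=int)
    free = free[spec.n_monomorphic :]
    hwe_idx = np.array(free[: spec.n_hwe_violators], dtype=int)
    free = free[spec.n_hwe_violators :]
    hi_miss_idx = np.array(free[: spec.n_high_missing_variants], dtype=int)

    G_auto[:, mono_idx] = 0
    # HWE violators: controls fully inbred (no heterozygotes) -> gross het deficit
    if hwe_idx.size:
        ctrl = ~is_case
        draws = rng.random((int(ctrl.sum()), hwe_idx.size))
        G_auto[np.ix_(ctrl, hwe_idx)] = 2 * (draws < maf[hwe_idx]).astype(np.int8)

    # ancestry outliers (controls) redrawn from diverged allele frequencies
    outlier_idx = np.arange(spec.n_case, spec.n_case + spec.n_outlier_ancestry)
    if outlier_idx.size:
        p_out = balding_nichols_frequencies(
            seeded_rng(spec.seed, "cohort", "outliers"), maf[:n_auto], spec.fst_outlier
        )
        keep_cols = np.ones(n_auto, dtype=bool)
        keep_cols[mono_idx] = False
        out_rng = seeded_rng(spec.seed, "cohort", "outlier-draws")
        block = _hwe_genotypes(out_rng, p_out[keep_cols], outlier_idx.size)
        G_auto[np.ix_(outlier_idx, np.flatnonzero(keep_cols))] = block

    # X-linked genotypes: females HWE, males hemizygous coded {0, 2}
    blocks = [G_auto]
    if spec.n_x_variants:
        x_rng = seeded_rng(spec.seed, "cohort", "xchrom")
        p_x = maf[n_auto:]
        G_x = np.empty((n_samples, spec.n_x_variants), dtype=np.int8)
        f = true_female
        G_x[f] = _hwe_genotypes(x_rng, p_x, int(f.sum()))
        G_x[~f] = 2 * (x_rng.random((int((~f).sum()), spec.n_x_variants)) < p_x).astype(np.int8)
        blocks.append(G_x)
    G = np.concatenate(blocks, axis=1)

    # related pairs: duplicate-with-noise among controls not used as outliers
    related_pairs: list[tuple[int, int]] = []
    rel_rng = seeded_rng(spec.seed, "cohort", "related")
    rel_start = spec.n_case + spec.n_outlier_ancestry
    for k in range(spec.n_related_pairs):
        a, b = rel_start + 2 * k, rel_start + 2 * k + 1
        G[b] = G[a]
        true_female[b] = true_female[a]
        flip = rel_rng.random(spec.n_variants) < 0.05
        flip[mono_idx] = False  # planted monomorphic columns stay constant
        redraw = _hwe_genotypes(rel_rng, maf, 1)[0]
        G[b, flip] = redraw[flip]
        related_pairs.append((a, b))

    # recorded sex: flip the label on the first n_sex_mismatches samples
    recorded_female = true_female.copy()
    mismatch_idx = np.arange(spec.n_sex_mismatches)
    recorded_female[mismatch_idx] = ~recorded_female[mismatch_idx]

    # missingness: background rate everywhere, boosted rows/columns where planted
    miss_rng = seeded_rng(spec.seed, "cohort", "missing")
    rate = np.full((n_samples, spec.n_variants), spec.missing_rate)
    hi_samp_idx = np.arange(n_samples - spec.n_high_missing_samples, n_samples)
    rate[hi_samp_idx, :] = np.maximum(rate[hi_samp_idx, :], spec.high_missing_rate)
    rate[:, hi_miss_idx] = np.maximum(rate[:, hi_miss_idx], spec.high_missing_rate)
    G[miss_rng.random(rate.shape) < rate] = MISSING

    samples = make_sample_frame(
        [f"S{i:05d}" for i in range(n_samples)],
        sex_reported=np.where(recorded_female, "female", "male"),
        phenotype=np.where(is_case, "case", "control"),
    )
    chrom = rng.integers(1, 23, size=n_auto).astype(str)
    variants = make_variant_frame(
        [f"rs{j:06d}" for j in range(spec.n_variants)],
        chrom=np.concatenate([chrom, np.full(spec.n_x_variants, "X")]),
        pos=np.arange(1, spec.n_variants + 1) * 1000,
    )
    dataset = GenotypeDataset(samples, variants, G)
    dataset.truth = CohortTruth(
        risk_loci=list(spec.risk_loci),
        monomorphic=mono_idx,
        hwe_violators=hwe_idx,
        high_missing_variants=hi_miss_idx,
        related_pairs=related_pairs,
        sex_mismatches=mismatch_idx,
        outlier_ancestry=outlier_idx,
        high_missing_samples=hi_samp_idx,
        maf=maf,
    )
    return dataset


def simulate_reference_panels(
    populations: list[tuple[str, int, float]],
    n_variants: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> dict[str, GenotypeDataset]:
    """Reference panels drawn around shared base frequencies (Balding-Nichols).

    ``populations`` is a list of (label, n_samples, fst_from_base); panels
    share one variant frame so they can be co-analysed directly.
    """
    if any(not 0 <= fst < 1 for _, _, fst in populations):
        raise ValueError("fst values must lie in [0, 1)")
    rng = seeded_rng(seed, "panels", "base")
    base = rng.uniform(*maf_range, size=n_variants)
    variants = make_variant_frame(
        [f"rs{j:06d}" for j in range(n_variants)],
        chrom=rng.integers(1, 23, size=n_variants).astype(str),
        pos=np.arange(1, n_variants + 1) * 1000,
    )
    panels: dict[str, GenotypeDataset] = {}
    for label, n, fst in populations:
        pop_rng = seeded_rng(seed, "panels", label)
        freqs = balding_nichols_frequencies(pop_rng, base, fst)
        G = _hwe_genotypes(pop_rng, freqs, n)
        samples = make_sample_frame(
            [f"{label}_{i:04d}" for i in range(n)],
            sex_reported=np.where(pop_rng.random(n) < 0.5, "female", "male"),
        )
        panel = GenotypeDataset(samples, variants.copy(), G)
        panel.truth = freqs  # population allele frequencies, for drawing extra subjects
        panels[label] = panel
    return panels


def sample_from_panel(
    panel: GenotypeDataset, n: int, seed: int, prefix: str = "extra"
) -> GenotypeDataset:
    """Fresh subjects drawn from a panel's population allele frequencies."""
    freqs = np.asarray(panel.truth, dtype=float)
    rng = seeded_rng(seed, "panel-extra", prefix)
    G = _hwe_genotypes(rng, freqs, n)
    samples = make_sample_frame(
        [f"{prefix}_{i:04d}" for i in range(n)],
        sex_reported=np.where(rng.random(n) < 0.5, "female", "male"),
    )
    out = GenotypeDataset(samples, panel.variants.copy(), G)
    out.truth = freqs
    return out


# ---------------------------------------------------------------------------
# toy evidence tables for SNP-to-gene mapping
# ---------------------------------------------------------------------------

def simulate_evidence(
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    seed: int,
    fraction_with_truth: float = 0.7,
) -> dict:
    """Toy VEP/QTL/chromatin/PPI/tractability tables with planted best genes.

    For a random subset of SNPs a target gene on the same chromosome is
    chosen and given strong QTL plus functional evidence; the remaining SNPs
    get no evidence rows at all.  Returns a dict with DataFrames under keys
    vep/qtl/chromatin/ppi/tractability and the planted ``truth`` mapping
    variant_id -> gene_id.
    """
    rng = seeded_rng(seed, "evidence")
    vep_rows, qtl_rows, chrom_rows = [], [], []
    truth: dict[str, str] = {}
    genes = genes.reset_index(drop=True)
    for _, snp in snps.iterrows():
        if rng.random() > fraction_with_truth:
            continue
        same_chrom = genes[genes["chrom"].astype(str) == str(snp["chrom"])]
        if same_chrom.empty:
            continue
        target = same_chrom.iloc[int(rng.integers(len(same_chrom)))]
        truth[snp["variant_id"]] = target["gene_id"]
        qtl_rows.append((snp["variant_id"], target["gene_id"], float(rng.uniform(0.8, 1.0))))
        vep_rows.append((snp["variant_id"], target["gene_id"], float(rng.uniform(0.6, 1.0))))
        if rng.random() < 0.5:
            chrom_rows.append((snp["variant_id"], target["gene_id"], float(rng.uniform(0.3, 1.0))))
        # a decoy gene with weak evidence, when one exists
        decoys = same_chrom[same_chrom["gene_id"] != target["gene_id"]]
        if not decoys.empty and rng.random() < 0.5:
            decoy = decoys.iloc[int(rng.integers(len(decoys)))]
            qtl_rows.append((snp["variant_id"], decoy["gene_id"], float(rng.uniform(0.0, 0.3))))
    gene_ids = list(genes["gene_id"])
    ppi_rows = []
    for _ in range(max(1, 3 * len(gene_ids))):
        a, b = rng.choice(len(gene_ids), size=2, replace=False)
        ppi_rows.append((gene_ids[a], gene_ids[b], float(rng.uniform(0.2, 1.0))))
    terms = ["Approved Drug", "Advanced Clinical", "Structure with Ligand", "Druggable Family"]
    tract_rows = [
        (g, terms[int(rng.integers(len(terms)))]) for g in gene_ids if rng.random() < 0.6
    ]
    return {
        "vep": pd.DataFrame(vep_rows, columns=["variant_id", "gene_id", "functional"]),
        "qtl": pd.DataFrame(qtl_rows, columns=["variant_id", "gene_id", "qtl"]),
        "chromatin": pd.DataFrame(chrom_rows, columns=["variant_id", "gene_id", "chromatin"]),
        "ppi": pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "confidence"]),
        "tractability": pd.DataFrame(tract_rows, columns=["gene_id", "term"]),
        "truth": truth,
    }
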