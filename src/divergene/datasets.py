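"""In-memory containers for case/control genotype data.

A :class:`GenotypeDataset` couples a sample table, a variant table and a
dense genotype-code matrix.  Genotype codes count the alternate allele
(0/1/2) for SNPs; X-linked male genotypes use {0, 2} (hemizygous mapped to
the homozygous codes); categorical variables (e.g. imputed HLA alleles,
collection centre) store a category index per sample.  Missing genotypes
are coded -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

MISSING = -1

SAMPLE_COLUMNS = ["sample_id", "sex_reported", "phenotype", "centre"]
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "is_categorical"]

X_CHROM_LABELS = frozenset({"X", "chrX", "23"})


def make_sample_frame(
    sample_ids,
    sex_reported=None,
    phenotype=None,
    centre=None,
) -> pd.DataFrame:
    """Build a normalised sample table.

    ``sex_reported`` takes values {male, female, unknown}; ``phenotype``
    takes {case, control} and may be missing only for supplementary
    (non-analysis) samples.
    """
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "sample_id": pd.Series(sample_ids, dtype=str),
            "sex_reported": pd.Series(
                sex_reported if sex_reported is not None else ["unknown"] * n, dtype=str
            ),
            "phenotype": pd.Series(
                phenotype if phenotype is not None else [None] * n, dtype=object
            ),
            "centre": pd.Series(centre if centre is not None else [None] * n, dtype=object),
        }
    )
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id: {dup!r}")
    return frame


def make_variant_frame(
    variant_ids,
    chrom,
    pos,
    ref=None,
    alt=None,
    is_categorical=None,
) -> pd.DataFrame:
    n = len(variant_ids)
    frame = pd.DataFrame(
        {
            "variant_id": pd.Series(variant_ids, dtype=str),
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref if ref is not None else ["A"] * n, dtype=object),
            "alt": pd.Series(alt if alt is not None else ["G"] * n, dtype=object),
            "is_categorical": pd.Series(
                is_categorical if is_categorical is not None else [False] * n, dtype=bool
            ),
        }
    )
    if frame["variant_id"].duplicated().any():
        dup = frame.loc[frame["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicated variant id: {dup!r}")
    positional = ~frame["is_categorical"]
    if (frame.loc[positional, "pos"] < 1).any():
        raise ValueError("positions must be >= 1 (1-based) for positional variants")
    frame.loc[frame["is_categorical"], ["ref", "alt"]] = None
    return frame


@dataclass
class GenotypeDataset:
    """Sample x variant genotype matrix with aligned metadata tables."""

    samples: pd.DataFrame
    variants: pd.DataFrame
    G: np.ndarray
    call_prob: np.ndarray | None = None
    truth: Any = None  # provenance record attached by the simulator

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.G = np.asarray(self.G)
        if self.G.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.call_prob is not None:
            self.call_prob = np.asarray(self.call_prob, dtype=float)
            if self.call_prob.shape != self.G.shape:
                raise ValueError("call_prob shape must match genotype matrix")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def phenotype_mask(self, label: str) -> np.ndarray:
        return (self.samples["phenotype"] == label).to_numpy()

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype_mask("case")

    @property
    def is_male(self) -> np.ndarray:
        return (self.samples["sex_reported"] == "male").to_numpy()

    @property
    def x_linked(self) -> np.ndarray:
        """Boolean mask over variants on the X chromosome."""
        return self.variants["chrom"].isin(X_CHROM_LABELS).to_numpy()

    # -- subsetting -------------------------------------------------------
    def take_samples(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            samples=self.samples.iloc[index],
            variants=self.variants,
            G=self.G[index, :],
            call_prob=None if self.call_prob is None else self.call_prob[index, :],
        )

    def take_variants(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            samples=self.samples,
            variants=self.variants.iloc[index],
            G=self.G[:, index],
            call_prob=None if self.call_prob is None else self.call_prob[:, index],
        )

    def select_samples(self, sample_ids) -> "GenotypeDataset":
        pos = pd.Index(self.samples["sample_id"]).get_indexer(list(sample_ids))
        if (pos < 0).any():
            raise KeyError("unknown sample id in selection")
        return self.take_samples(pos)

    def select_variants(self, variant_ids) -> "GenotypeDataset":
        pos = pd.Index(self.variants["variant_id"]).get_indexer(list(variant_ids))
        if (pos < 0).any():
            raise KeyError("unknown variant id in selection")
        return self.take_variants(pos)

    def missing_mask(self) -> np.ndarray:
        return self.G == MISSING

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def variant_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def equals(self, other: "GenotypeDataset") -> bool:
        if self.G.shape != other.G.shape:
            return False
        same_g = np.array_equal(self.G, other.G)
        same_s = self.samples[SAMPLE_COLUMNS].equals(other.samples[SAMPLE_COLUMNS])
        same_v = self.variants[VARIANT_COLUMNS].equals(other.variants[VARIANT_COLUMNS])
        return bool(same_g and same_s and same_v)


def concat_samples(datasets: list[GenotypeDataset]) -> GenotypeDataset:
    """Stack datasets sample-wise; variant frames must agree on variant_id."""
    base = datasets[0]
    for other in datasets[1:]:
        if not np.array_equal(base.variant_ids, other.variant_ids):
            raise ValueError("cannot stack datasets with different variant sets")
    samples = pd.concat([d.samples for d in datasets], ignore_index=True)
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids across stacked datasets")
    G = np.vstack([d.G for d in datasets])
    return GenotypeDataset(samples=samples, variants=base.variants.copy(), G=G)
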