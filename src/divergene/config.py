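"""Run configuration: every numeric threshold the pipeline uses, in one place.

Defaults follow the published analysis settings (call-probability floor 0.90,
5% missingness caps, HWE p floor 1e-8, relatedness MAF floor 0.48, ancestry
alpha 0.2, 5 retained components, 10 000 permutations, Sidak alpha 0.05,
LD r^2 >= 0.6, 40 kb gene window + 1 kb promoter, evidence weights
0.35/0.35/0.2/0.1, TOPSIS >= 0.4, PPI confidence >= 0.5 with >= 2 seed links).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # genotype intake
    call_prob_min: float = 0.90
    # univariate QC
    sample_missing_max: float = 0.05
    variant_missing_max: float = 0.05
    hwe_p_min: float = 1e-8
    relatedness_maf_min: float = 0.48
    relatedness_n_snps: int = 5000
    relatedness_identity_min: float = 0.8
    sex_het_male_max: float = 0.02
    sex_het_female_min: float = 0.20
    # ancestry homogenisation
    ancestry_alpha: float = 0.20
    ancestry_k_clusters: int = 1
    ancestry_keep_tail: bool = False  # complementary reading of the alpha percentile
    # LBF + PCA + permutation
    pseudocount: float = 0.5
    n_components: int = 5
    n_permutations: int = 10_000
    fwer_alpha: float = 0.05
    two_sided: bool = False
    # SNP-to-gene
    ld_r2_min: float = 0.6
    ld_window_bp: int = 1_000_000
    gene_window_bp: int = 40_000
    promoter_bp: int = 1_000
    weight_functional: float = 0.35
    weight_qtl: float = 0.35
    weight_distance: float = 0.20
    weight_chromatin: float = 0.10
    topsis_min: float = 0.4
    # PPI network expansion
    ppi_score_min: float = 0.5
    ppi_min_links: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "call_prob_min",
            "sample_missing_max",
            "variant_missing_max",
            "hwe_p_min",
            "relatedness_maf_min",
            "relatedness_identity_min",
            "ancestry_alpha",
            "fwer_alpha",
            "ld_r2_min",
            "topsis_min",
            "ppi_score_min",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        weights = self.evidence_weights
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError(f"evidence weights must sum to 1, got {weights}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @property
    def evidence_weights(self) -> dict[str, float]:
        return {
            "functional": self.weight_functional,
            "qtl": self.weight_qtl,
            "distance": self.weight_distance,
            "chromatin": self.weight_chromatin,
        }

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat TOML file; keyword overrides (e.g. CLI flags) win."""
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool):
                rendered = "true" if value else "false"
            elif isinstance(value, str):
                rendered = f'"{value}"'
            else:
                rendered = repr(value)
            lines.append(f"{f.name} = {rendered}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


DEFAULT_CONFIG = RunConfig()
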