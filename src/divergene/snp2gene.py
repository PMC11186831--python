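"""Variant-to-gene mapping, TOPSIS prioritisation, tractability, PPI expansion.

Significant variants are expanded to proxies in high LD (r^2 >= 0.6, squared
Pearson correlation of unphased dosages within a 1 Mb window), proxies are
linked to genes by proximity (< 40 kb from the gene boundary extended by a
1 kb strand-aware promoter) or by explicit functional/QTL/chromatin evidence,
and each (variant, gene) row is scored by TOPSIS against the theoretical best
(1,1,1,1) and worst (0,0,0,0) evidence profiles with weights functional 0.35,
QTL 0.35, distance 0.2, chromatin 0.1.  Genes scoring >= 0.4 form the seed
set for network expansion over a confidence-filtered protein-protein
interaction edge list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset
from .utils import logger

EVIDENCE_CRITERIA = ("functional", "qtl", "distance", "chromatin")
DEFAULT_WEIGHTS = {"functional": 0.35, "qtl": 0.35, "distance": 0.2, "chromatin": 0.1}

# severity of predicted variant consequences, on [0, 1] (VEP-style ordering)
CONSEQUENCE_SEVERITY = {
    "transcript_ablation": 1.0,
    "stop_gained": 1.0,
    "frameshift_variant": 1.0,
    "stop_lost": 0.95,
    "start_lost": 0.95,
    "splice_acceptor_variant": 0.95,
    "splice_donor_variant": 0.95,
    "missense_variant": 0.7,
    "inframe_insertion": 0.7,
    "inframe_deletion": 0.7,
    "splice_region_variant": 0.5,
    "synonymous_variant": 0.3,
    "5_prime_UTR_variant": 0.25,
    "3_prime_UTR_variant": 0.25,
    "upstream_gene_variant": 0.15,
    "downstream_gene_variant": 0.15,
    "intron_variant": 0.1,
    "intergenic_variant": 0.05,
}

# drug-tractability term scores (maximum over a gene's terms is its score)
TRACTABILITY_TERMS = {
    "Approved Drug": 1.0,
    "Advanced Clinical": 0.9,
    "Phase 1 Clinical": 0.8,
    "Structure with Ligand": 0.5,
    "UniProt loc high conf": 0.5,
    "Literature": 0.5,
    "GO CC high conf": 0.45,
    "High-Quality Ligand": 0.4,
    "UniProt loc med conf": 0.4,
    "UniProt Ubiquitination": 0.4,
    "High-Quality Pocket": 0.3,
    "UniProt SigP or TMHMM": 0.3,
    "Database Ubiquitination": 0.3,
    "Med-Quality Pocket": 0.2,
    "GO CC med conf": 0.2,
    "Half-life Data": 0.2,
    "Druggable Family": 0.1,
    "Human Protein Atlas loc": 0.1,
    "Small Molecule Binder": 0.1,
}


# ---------------------------------------------------------------------------
# LD expansion
# ---------------------------------------------------------------------------

def ld_r2(panel: GenotypeDataset, a: str, b: str) -> float:
    """Squared Pearson correlation of dosages (composite LD, unphased)."""
    ia = int(np.flatnonzero(panel.variant_ids == a)[0])
    ib = int(np.flatnonzero(panel.variant_ids == b)[0])
    return _pairwise_r2(panel.G[:, ia], panel.G[:, ib])


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_expand(
    seeds: list[str],
    panel: GenotypeDataset,
    r2_min: float = 0.6,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Proxy variants in high LD with each seed.

    Returns rows (seed_id, proxy_id, r2); every seed is its own proxy with
    r2 = 1; proxies are panel variants on the seed's chromosome within
    ``window_bp`` whose dosage r^2 is at least ``r2_min``.  A seed absent
    from the panel is kept with itself only.
    """
    if panel.n_samples < 50:
        logger.warning("LD panel has %d samples (< 50); r2 will be noisy", panel.n_samples)
    variants = panel.variants
    index = pd.Index(variants["variant_id"])
    rows = []
    for seed in seeds:
        pos = index.get_indexer([seed])[0]
        if pos < 0:
            logger.warning("seed %s not in the LD panel; kept with itself only", seed)
            rows.append((seed, seed, 1.0))
            continue
        chrom = variants.iloc[pos]["chrom"]
        centre = variants.iloc[pos]["pos"]
        near = (
            (variants["chrom"] == chrom)
            & (variants["pos"] - centre).abs().le(window_bp)
            & ~variants["is_categorical"]
        ).to_numpy()
        x = panel.G[:, pos]
        for j in np.flatnonzero(near):
            if j == pos:
                rows.append((seed, seed, 1.0))
                continue
            r2 = _pairwise_r2(x, panel.G[:, j])
            if np.isfinite(r2) and r2 >= r2_min:
                rows.append((seed, variants.iloc[j]["variant_id"], float(r2)))
    return pd.DataFrame(rows, columns=["seed_id", "proxy_id", "r2"])


# ---------------------------------------------------------------------------
# evidence collection
# ---------------------------------------------------------------------------

def _interval_distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return int(start - pos) if pos < start else int(pos - end)


def _promoter_extended(gene: pd.Series, promoter_bp: int) -> tuple[int, int]:
    start, end, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
    if strand == "+":
        return start - promoter_bp, end
    if strand == "-":
        return start, end + promoter_bp
    logger.warning("gene %s has unknown strand; extending the promoter on both sides",
                   gene["gene_id"])
    return start - promoter_bp, end + promoter_bp


def collect_evidence(
    proxies: pd.DataFrame,
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    vep: pd.DataFrame | None = None,
    qtl: pd.DataFrame | None = None,
    chromatin: pd.DataFrame | None = None,
    gene_window_bp: int = 40_000,
    promoter_bp: int = 1_000,
) -> pd.DataFrame:
    """Build (seed, proxy, gene) evidence rows with criterion values in [0, 1].

    A row exists iff the proxy lies strictly within ``gene_window_bp`` of the
    promoter-extended gene interval, or a functional/QTL/chromatin record
    links proxy and gene.  The distance criterion is the linear proximity
    ``max(0, 1 - distance / gene_window_bp)``; absent evidence scores 0.
    The ``vep`` table may carry either a ``functional`` value in [0, 1] or a
    ``consequence`` term mapped through :data:`CONSEQUENCE_SEVERITY`.
    """
    snp_pos = snps.set_index("variant_id")[["chrom", "pos"]]

    def evidence_lookup(table, value_col):
        if table is None or table.empty:
            return {}
        table = table.copy()
        if value_col == "functional" and "functional" not in table.columns:
            unknown = set(table["consequence"]) - set(CONSEQUENCE_SEVERITY)
            if unknown:
                raise ValueError(f"unknown consequence terms: {sorted(unknown)}")
            table["functional"] = table["consequence"].map(CONSEQUENCE_SEVERITY)
        return table.groupby(["variant_id", "gene_id"])[value_col].max().to_dict()

    vep_map = evidence_lookup(vep, "functional")
    qtl_map = evidence_lookup(qtl, "qtl")
    chrom_map = evidence_lookup(chromatin, "chromatin")

    rows = []
    for seed_id, proxy_id in proxies[["seed_id", "proxy_id"]].itertuples(index=False):
        if proxy_id not in snp_pos.index:
            continue
        chrom, pos = snp_pos.loc[proxy_id, ["chrom", "pos"]]
        r2 = float(
            proxies.loc[
                (proxies["seed_id"] == seed_id) & (proxies["proxy_id"] == proxy_id), "r2"
            ].iloc[0]
        )
        candidates = genes[genes["chrom"].astype(str) == str(chrom)]
        linked_genes = {
            g for (v, g) in list(vep_map) + list(qtl_map) + list(chrom_map) if v == proxy_id
        }
        for _, gene in candidates.iterrows():
            lo, hi = _promoter_extended(gene, promoter_bp)
            distance = _interval_distance(int(pos), lo, hi)
            in_window = distance < gene_window_bp
            has_evidence = gene["gene_id"] in linked_genes
            if not in_window and not has_evidence:
                continue
            key = (proxy_id, gene["gene_id"])
            rows.append(
                {
                    "seed_id": seed_id,
                    "proxy_id": proxy_id,
                    "r2": r2,
                    "gene_id": gene["gene_id"],
                    "distance_bp": distance,
                    "functional": float(vep_map.get(key, 0.0)),
                    "qtl": float(qtl_map.get(key, 0.0)),
                    "distance": max(0.0, 1.0 - distance / gene_window_bp) if in_window else 0.0,
                    "chromatin": float(chrom_map.get(key, 0.0)),
                }
            )
        # evidence rows to genes outside the candidate chromosome subset
        for gene_id in linked_genes - set(candidates["gene_id"]):
            gene_rows = genes[genes["gene_id"] == gene_id]
            if gene_rows.empty:
                continue
            key = (proxy_id, gene_id)
            rows.append(
                {
                    "seed_id": seed_id, "proxy_id": proxy_id, "r2": r2, "gene_id": gene_id,
                    "distance_bp": -1, "functional": float(vep_map.get(key, 0.0)),
                    "qtl": float(qtl_map.get(key, 0.0)), "distance": 0.0,
                    "chromatin": float(chrom_map.get(key, 0.0)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "seed_id", "proxy_id", "r2", "gene_id", "distance_bp",
            "functional", "qtl", "distance", "chromatin",
        ],
    )


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------

def topsis_scores(values: np.ndarray, weights: dict[str, float] | np.ndarray = None) -> np.ndarray:
    """TOPSIS closeness to the theoretical best evidence profile.

    ``values``: (n_rows, 4) criterion matrix in [0, 1] ordered as
    (functional, qtl, distance, chromatin).  The ideal is all ones, the
    anti-ideal all zeros; distances are weighted Euclidean and the score is
    d- / (d+ + d-), in [0, 1].  An all-zero row scores 0.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if weights is None:
        weights = DEFAULT_WEIGHTS
    if isinstance(weights, dict):
        w = np.array([weights[c] for c in EVIDENCE_CRITERIA])
    else:
        w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("criterion weights must sum to 1")
    if values.min() < -1e-12 or values.max() > 1 + 1e-12:
        raise ValueError("criterion values must lie in [0, 1]")
    v = values * w[None, :]
    d_plus = np.linalg.norm(v - w[None, :], axis=1)
    d_minus = np.linalg.norm(v, axis=1)
    denom = d_plus + d_minus
    return np.divide(d_minus, denom, out=np.zeros_like(denom), where=denom > 0)


def topsis_score_table(
    rows: pd.DataFrame,
    weights: dict[str, float] | None = None,
    topsis_min: float = 0.4,
) -> pd.DataFrame:
    """Score evidence rows; aggregate per (seed, gene) and per gene by maximum."""
    if rows.empty:
        return pd.DataFrame(
            columns=["seed_id", "gene_id", "topsis", "passes"]
        )
    scored = rows.copy()
    scored["topsis"] = topsis_scores(scored[list(EVIDENCE_CRITERIA)].to_numpy(), weights)
    per_pair = (
        scored.groupby(["seed_id", "gene_id"], as_index=False)["topsis"].max()
    )
    per_pair["passes"] = per_pair["topsis"] >= topsis_min
    return per_pair


def gene_scores(per_pair: pd.DataFrame, topsis_min: float = 0.4) -> pd.DataFrame:
    """Per-gene maximum TOPSIS over all seed variants."""
    if per_pair.empty:
        return pd.DataFrame(columns=["gene_id", "topsis", "passes"])
    out = per_pair.groupby("gene_id", as_index=False)["topsis"].max()
    out["passes"] = out["topsis"] >= topsis_min
    return out


# ---------------------------------------------------------------------------
# tractability
# ---------------------------------------------------------------------------

def tractability_score(terms: list[str], score_table: dict[str, float] | None = None) -> float:
    """Maximum term score for a gene; no terms -> 0."""
    table = TRACTABILITY_TERMS if score_table is None else score_table
    unknown = [t for t in terms if t not in table]
    if unknown:
        raise ValueError(
            f"unknown tractability terms {unknown}; valid terms: {sorted(table)}"
        )
    return max((table[t] for t in terms), default=0.0)


def tractability_table(gene_terms: pd.DataFrame) -> pd.DataFrame:
    """Per-gene tractability from a (gene_id, term) long table."""
    scores = gene_terms.groupby("gene_id")["term"].apply(
        lambda terms: tractability_score(list(terms))
    )
    return scores.rename("tractability").reset_index()


# ---------------------------------------------------------------------------
# PPI network expansion
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    nodes: pd.DataFrame  # gene_id, is_seed
    edges: pd.DataFrame  # gene_a, gene_b, confidence

    def graph(self):
        import networkx as nx

        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["gene_id"], is_seed=bool(row["is_seed"]))
        for _, row in self.edges.iterrows():
            g.add_edge(row["gene_a"], row["gene_b"], confidence=float(row["confidence"]))
        return g


def expand_ppi(
    seed_genes: list[str],
    edges: pd.DataFrame,
    score_min: float = 0.5,
    min_links: int = 2,
) -> PPINetwork:
    """Filtered interaction network around the seed genes.

    Edges below ``score_min`` confidence are dropped; among the remainder,
    seed-seed edges are kept with no further condition, and a non-seed
    interactor is retained iff it keeps edges to at least ``min_links``
    distinct seed genes.
    """
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        raise ValueError("edge confidences must lie in [0, 1]")
    seeds = set(seed_genes)
    strong = edges[edges["confidence"] >= score_min].copy()
    a_seed = strong["gene_a"].isin(seeds)
    b_seed = strong["gene_b"].isin(seeds)
    seed_seed = strong[a_seed & b_seed]
    half = strong[a_seed ^ b_seed].copy()
    half["interactor"] = np.where(half["gene_a"].isin(seeds), half["gene_b"], half["gene_a"])
    half["seed"] = np.where(half["gene_a"].isin(seeds), half["gene_a"], half["gene_b"])
    links = half.groupby("interactor")["seed"].nunique()
    retained = set(links[links >= min_links].index)
    kept_half = half[half["interactor"].isin(retained)]
    out_edges = pd.concat(
        [seed_seed, kept_half[["gene_a", "gene_b", "confidence"]]], ignore_index=True
    )
    node_ids = sorted(seeds | retained)
    nodes = pd.DataFrame({"gene_id": node_ids, "is_seed": [g in seeds for g in node_ids]})
    return PPINetwork(nodes=nodes, edges=out_edges)


# ---------------------------------------------------------------------------
# end-to-end variant -> gene pipeline
# ---------------------------------------------------------------------------

def map_variants_to_genes(
    seed_variants: list[str],
    panel: GenotypeDataset,
    genes: pd.DataFrame,
    vep: pd.DataFrame | None = None,
    qtl: pd.DataFrame | None = None,
    chromatin: pd.DataFrame | None = None,
    config=None,
) -> dict:
    """LD expansion -> evidence -> TOPSIS, returning all intermediate tables."""
    from .config import DEFAULT_CONFIG

    config = config or DEFAULT_CONFIG
    proxies = ld_expand(
        seed_variants, panel, r2_min=config.ld_r2_min, window_bp=config.ld_window_bp
    )
    evidence = collect_evidence(
        proxies, genes, panel.variants, vep=vep, qtl=qtl, chromatin=chromatin,
        gene_window_bp=config.gene_window_bp, promoter_bp=config.promoter_bp,
    )
    pair_scores = topsis_score_table(evidence, config.evidence_weights, config.topsis_min)
    per_gene = pair_scores.groupby("gene_id", as_index=False)["topsis"].max()
    per_gene["passes"] = per_gene["topsis"] >= config.topsis_min
    return {
        "proxies": proxies,
        "evidence": evidence,
        "pair_scores": pair_scores,
        "gene_scores": per_gene,
        "mapped_genes": sorted(per_gene.loc[per_gene["passes"], "gene_id"]),
    }
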