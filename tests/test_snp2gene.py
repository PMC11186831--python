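import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divergene as dg
from divergene.datasets import MISSING
from divergene.snp2gene import (
    CONSEQUENCE_SEVERITY,
    DEFAULT_WEIGHTS,
    EVIDENCE_CRITERIA,
    collect_evidence,
    expand_ppi,
    topsis_scores,
    tractability_score,
    tractability_table,
)


def topsis_oracle(row, weights=(0.35, 0.35, 0.2, 0.1)):
    """Independent scalar-loop TOPSIS: weighted distances to (1,..) and (0,..)."""
    import math

    d_plus = math.sqrt(sum((w * x - w * 1.0) ** 2 for w, x in zip(weights, row)))
    d_minus = math.sqrt(sum((w * x - w * 0.0) ** 2 for w, x in zip(weights, row)))
    if d_plus + d_minus == 0:
        return 0.0
    return d_minus / (d_plus + d_minus)


def _panel(G, chrom=None, pos=None):
    n, m = G.shape
    samples = dg.make_sample_frame([f"s{i}" for i in range(n)])
    variants = dg.make_variant_frame(
        [f"v{j}" for j in range(m)],
        chrom=chrom if chrom is not None else ["1"] * m,
        pos=pos if pos is not None else np.arange(1, m + 1) * 100,
    )
    return dg.GenotypeDataset(samples, variants, np.asarray(G, dtype=np.int8))


# ---------------------------------------------------------------------------
# LD expansion
# ---------------------------------------------------------------------------

def test_duplicated_column_is_a_proxy():
    rng = np.random.default_rng(0)
    G = rng.integers(0, 3, size=(100, 4))
    G[:, 1] = G[:, 0]
    proxies = dg.ld_expand(["v0"], _panel(G), r2_min=0.6)
    got = dict(zip(proxies["proxy_id"], proxies["r2"]))
    assert got["v0"] == 1.0
    assert got["v1"] == pytest.approx(1.0)


def test_independent_variants_excluded():
    rng = np.random.default_rng(1)
    p = 0.3
    G = (rng.random((500, 2)) < p).astype(int) + (rng.random((500, 2)) < p).astype(int)
    proxies = dg.ld_expand(["v0"], _panel(G), r2_min=0.6)
    assert set(proxies["proxy_id"]) == {"v0"}


def test_partial_flip_matches_direct_correlation():
    rng = np.random.default_rng(2)
    x = (rng.random(500) < 0.4).astype(int) + (rng.random(500) < 0.4).astype(int)
    y = x.copy()
    flip = rng.random(500) < 0.2
    y[flip] = rng.integers(0, 3, flip.sum())
    r2_direct = np.corrcoef(x, y)[0, 1] ** 2
    G = np.column_stack([x, y])
    proxies = dg.ld_expand(["v0"], _panel(G), r2_min=0.0)
    got = dict(zip(proxies["proxy_id"], proxies["r2"]))
    assert got["v1"] == pytest.approx(r2_direct, rel=1e-10)


def test_ld_window_and_missing_seed():
    rng = np.random.default_rng(3)
    G = rng.integers(0, 3, size=(80, 3))
    G[:, 2] = G[:, 0]
    panel = _panel(G, pos=[100, 200, 5_000_000])  # v2 outside a 1 Mb window
    proxies = dg.ld_expand(["v0"], panel, r2_min=0.6)
    assert "v2" not in set(proxies["proxy_id"])
    lone = dg.ld_expand(["absent"], panel, r2_min=0.6)
    assert lone.to_dict("records") == [{"seed_id": "absent", "proxy_id": "absent", "r2": 1.0}]


def test_proxy_relation_is_symmetric():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 3, 300)
    y = x.copy()
    flip = rng.random(300) < 0.1
    y[flip] = rng.integers(0, 3, flip.sum())
    # build a small panel of correlated + independent columns
    G = np.column_stack([x, y, rng.integers(0, 3, 300)])
    panel = _panel(G)
    fwd = dg.ld_expand(["v0"], panel, r2_min=0.6)
    rev = dg.ld_expand(["v1"], panel, r2_min=0.6)
    assert ("v1" in set(fwd["proxy_id"])) == ("v0" in set(rev["proxy_id"]))


# ---------------------------------------------------------------------------
# evidence collection
# ---------------------------------------------------------------------------

GENES = pd.DataFrame(
    {
        "gene_id": ["PLUS", "MINUS"],
        "chrom": ["1", "1"],
        "start": [1_000_000, 2_000_000],
        "end": [1_050_000, 2_050_000],
        "strand": ["+", "-"],
    }
)


def _proxies(*variant_ids):
    return pd.DataFrame(
        {"seed_id": variant_ids, "proxy_id": variant_ids, "r2": [1.0] * len(variant_ids)}
    )


def _snps(positions):
    return dg.make_variant_frame(
        [f"rs{i}" for i in range(len(positions))], chrom=["1"] * len(positions), pos=positions
    )


def test_variant_inside_gene_has_proximity_one():
    ev = collect_evidence(_proxies("rs0"), GENES, _snps([1_010_000]))
    row = ev[ev["gene_id"] == "PLUS"].iloc[0]
    assert row["distance_bp"] == 0 and row["distance"] == 1.0


def test_window_boundary_is_strict():
    """39,999 bp beyond the promoter-extended edge maps; 40,001 bp does not."""
    promoter_edge = 1_000_000 - 1_000  # plus-strand promoter extends upstream
    near = collect_evidence(_proxies("rs0"), GENES, _snps([promoter_edge - 39_999]))
    far = collect_evidence(_proxies("rs0"), GENES, _snps([promoter_edge - 40_001]))
    assert (near["gene_id"] == "PLUS").any()
    assert not (far["gene_id"] == "PLUS").any()
    at = collect_evidence(_proxies("rs0"), GENES, _snps([promoter_edge - 40_000]))
    assert not (at["gene_id"] == "PLUS").any()  # strictly less than 40 kb


def test_minus_strand_promoter_is_downstream_in_genome_coordinates():
    """500 bp beyond a minus-strand gene's genomic end is inside its promoter."""
    ev = collect_evidence(_proxies("rs0"), GENES, _snps([2_050_500]))
    row = ev[ev["gene_id"] == "MINUS"].iloc[0]
    assert row["distance_bp"] == 0 and row["distance"] == 1.0
    # the plus-strand gene has no promoter on its downstream side
    ev2 = collect_evidence(_proxies("rs0"), GENES, _snps([1_050_500]))
    row2 = ev2[ev2["gene_id"] == "PLUS"].iloc[0]
    assert row2["distance_bp"] == 500


def test_qtl_evidence_links_distant_gene():
    qtl = pd.DataFrame({"variant_id": ["rs0"], "gene_id": ["MINUS"], "qtl": [0.9]})
    ev = collect_evidence(_proxies("rs0"), GENES, _snps([1_010_000]), qtl=qtl)
    minus = ev[ev["gene_id"] == "MINUS"].iloc[0]
    assert minus["qtl"] == 0.9 and minus["distance"] == 0.0


def test_consequence_terms_map_to_severity():
    vep = pd.DataFrame(
        {"variant_id": ["rs0"], "gene_id": ["PLUS"], "consequence": ["missense_variant"]}
    )
    ev = collect_evidence(_proxies("rs0"), GENES, _snps([1_010_000]), vep=vep)
    assert ev[ev["gene_id"] == "PLUS"]["functional"].iloc[0] == CONSEQUENCE_SEVERITY[
        "missense_variant"
    ]
    with pytest.raises(ValueError, match="unknown consequence"):
        collect_evidence(
            _proxies("rs0"), GENES, _snps([1_010_000]),
            vep=pd.DataFrame(
                {"variant_id": ["rs0"], "gene_id": ["PLUS"], "consequence": ["nonsense_term"]}
            ),
        )


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------

def test_topsis_anchors():
    assert topsis_scores([[1, 1, 1, 1]])[0] == pytest.approx(1.0)
    assert topsis_scores([[0, 0, 0, 0]])[0] == pytest.approx(0.0)


def test_topsis_matches_independent_oracle():
    row = [0.0, 1.0, 1.0, 0.0]
    assert topsis_scores([row])[0] == pytest.approx(topsis_oracle(row), abs=1e-12)
    rng = np.random.default_rng(5)
    rows = rng.random((50, 4))
    expected = [topsis_oracle(r) for r in rows]
    np.testing.assert_allclose(topsis_scores(rows), expected, atol=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=4, max_size=4),
    st.integers(min_value=0, max_value=3),
    st.floats(min_value=0, max_value=1),
)
def test_topsis_monotone_in_each_criterion(row, idx, bump):
    improved = list(row)
    improved[idx] = min(1.0, improved[idx] + bump)
    s0, s1 = topsis_scores([row, improved])
    assert s1 >= s0 - 1e-12


def test_planted_gene_wins_topsis():
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(6)],
            "chrom": ["1", "1", "2", "2", "3", "3"],
            "start": np.arange(6) * 200_000 + 1,
            "end": np.arange(6) * 200_000 + 30_000,
            "strand": ["+"] * 6,
        }
    )
    snps = dg.make_variant_frame(
        [f"rs{i}" for i in range(12)],
        chrom=[str(1 + i % 3) for i in range(12)],
        pos=(np.arange(12) * 90_000 + 1000) % 500_000 + 1,
    )
    sim = dg.simulate_evidence(genes, snps, seed=13)
    wins = 0
    total = 0
    for vid, gid in sim["truth"].items():
        prox = _proxies(vid)
        ev = collect_evidence(
            prox, genes, snps, vep=sim["vep"], qtl=sim["qtl"], chromatin=sim["chromatin"]
        )
        scores = dg.topsis_score_table(ev)
        if scores.empty:
            continue
        total += 1
        best = scores.loc[scores["topsis"].idxmax(), "gene_id"]
        wins += best == gid
    assert total > 0 and wins / total >= 0.95


# ---------------------------------------------------------------------------
# tractability
# ---------------------------------------------------------------------------

def test_tractability_scores():
    assert tractability_score(["Approved Drug", "Med-Quality Pocket"]) == 1.0
    assert tractability_score(["Druggable Family"]) == 0.1
    assert tractability_score([]) == 0.0
    with pytest.raises(ValueError, match="unknown tractability"):
        tractability_score(["Not A Term"])
    table = tractability_table(
        pd.DataFrame({"gene_id": ["A", "A", "B"], "term": ["Literature", "Approved Drug", "Half-life Data"]})
    )
    assert dict(zip(table["gene_id"], table["tractability"])) == {"A": 1.0, "B": 0.2}


# ---------------------------------------------------------------------------
# PPI expansion
# ---------------------------------------------------------------------------

def test_ppi_three_rule_toy_graph():
    edges = pd.DataFrame(
        [
            ("X", "A", 0.6), ("X", "B", 0.7),   # X: two strong seed links -> kept
            ("Y", "A", 0.9),                      # Y: one seed link -> dropped
            ("Z", "A", 0.4), ("Z", "B", 0.9),   # Z: one edge below 0.5 -> dropped
        ],
        columns=["gene_a", "gene_b", "confidence"],
    )
    net = expand_ppi(["A", "B"], edges, score_min=0.5, min_links=2)
    kept = set(net.nodes.loc[~net.nodes["is_seed"], "gene_id"])
    assert kept == {"X"}
    assert set(net.nodes["gene_id"]) == {"A", "B", "X"}


def test_ppi_seed_seed_edges_need_no_link_count():
    edges = pd.DataFrame(
        [("A", "B", 0.8), ("A", "C", 0.4)], columns=["gene_a", "gene_b", "confidence"]
    )
    net = expand_ppi(["A", "B", "C"], edges, score_min=0.5, min_links=2)
    pairs = {frozenset((a, b)) for a, b in net.edges[["gene_a", "gene_b"]].to_numpy()}
    assert frozenset(("A", "B")) in pairs
    assert frozenset(("A", "C")) not in pairs  # below the confidence floor
    g = net.graph()
    assert g.number_of_edges() == 1


def test_ppi_retained_interactor_invariant():
    rng = np.random.default_rng(6)
    seeds = [f"S{i}" for i in range(5)]
    others = [f"I{i}" for i in range(20)]
    rows = []
    for _ in range(200):
        a = rng.choice(seeds + others)
        b = rng.choice(seeds + others)
        if a != b:
            rows.append((a, b, float(rng.random())))
    net = expand_ppi(seeds, pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]))
    for gene in net.nodes.loc[~net.nodes["is_seed"], "gene_id"]:
        sub = net.edges[(net.edges["gene_a"] == gene) | (net.edges["gene_b"] == gene)]
        partners = set(sub["gene_a"]) | set(sub["gene_b"])
        assert len(partners & set(seeds)) >= 2
        assert (sub["confidence"] >= 0.5).all()
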