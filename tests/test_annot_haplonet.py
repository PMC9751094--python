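"""Annotation comparison and haplotype-network construction."""

import networkx as nx
import pandas as pd
import pytest

from plastomarker import annot_compare as ac
from plastomarker import haplonet as hn
from plastomarker.intervals import CircularInterval as CI
from plastomarker.io import FeaturePart, GeneFeature


def _gene(name, kind, start, end, strand="+", sid="x"):
    return GeneFeature(name, kind, (FeaturePart(CI(start, end), strand),), sid)


def test_inventory_counts_unique_and_duplicates():
    feats = [
        _gene("trnA-UGC", "tRNA", 10, 80),
        _gene("trnA-UGC", "tRNA", 500, 570),
        _gene("rbcL", "protein_coding", 100, 400),
    ]
    inv = ac.gene_inventory(feats, "x")
    assert inv.unique_total == 2 and inv.total_features == 3
    assert inv.copy_number["trnA-UGC"] == 2
    assert inv.unique_by_kind["tRNA"] == {"trnA-UGC"}


def test_inventory_nameless_feature_raises():
    with pytest.raises(ValueError, match="without a name"):
        ac.gene_inventory([_gene("", "tRNA", 0, 10)])


def test_family_inventories_and_cnv(micro):
    invs = {sid: ac.gene_inventory(f, sid) for sid, f in micro.features.items()}
    uniq = {sid: inv.unique_total for sid, inv in invs.items()}
    assert len(set(uniq.values())) == 1  # same unique gene set in all samples
    for inv in invs.values():
        assert inv.total_features >= inv.unique_total
        assert sum(len(v) for v in inv.unique_by_kind.values()) == inv.unique_total
    cnv = ac.copy_number_diff(invs)
    # exactly the planted extra trnQ-UUG copy in lb varies
    assert list(cnv.index) == ["trnQ-UUG"]
    assert cnv.loc["trnQ-UUG"].to_dict() == {
        "shb": 1, "rb": 1, "nhb": 1, "lb": 2, "bb": 1, "cb": 1
    }


def test_identical_inventories_give_empty_cnv(micro):
    f = micro.features["shb"]
    invs = {"a": ac.gene_inventory(f, "a"), "b": ac.gene_inventory(f, "b")}
    assert ac.copy_number_diff(invs).empty


def test_region_membership_and_fractions(micro, micro_analysis):
    sid = "shb"
    part = micro_analysis.partitions[sid]
    rm = ac.region_membership(micro.features[sid], part)
    assert rm["regions"]["SSC"] == ["ndhF"]
    assert rm["junction"] == ["psbA"]
    # IR genes appear in both IR copies
    assert "rrn16" in rm["regions"]["IRA"] and "rrn16" in rm["regions"]["IRB"]
    covered = set(rm["junction"]).union(*rm["regions"].values())
    assert covered == {f.name for f in micro.features[sid]}
    fr = rm["kind_fractions_pct"]["protein_coding"]
    assert fr["LSC"] > fr["SSC"]


def test_splicing_report_counts_and_trans_candidates(micro):
    sp = ac.splicing_report(micro.features["shb"], 20_000)
    assert sp["n_intron_genes"] == 2  # petB and rps12
    assert sp["trans_splicing_candidates"] == ["rps12"]  # mixed strands
    single = _gene("rbcL", "protein_coding", 0, 100)
    sp2 = ac.splicing_report([single], 1_000)
    assert sp2["n_intron_genes"] == 0


def test_network_two_samples_single_edge():
    steps = pd.DataFrame([[0, 2], [2, 0]], index=["a", "b"], columns=["a", "b"])
    g = hn.build_network(steps)
    assert list(g.edges(data="weight")) == [("a", "b", 2)]


def test_network_collinear_path_mst_forced():
    steps = pd.DataFrame(
        [[0, 1, 2], [1, 0, 1], [2, 1, 0]],
        index=list("ABC"), columns=list("ABC"),
    )
    g = hn.build_network(steps, extra_edge_slack=0)
    assert set(g.edges) == {("A", "B"), ("B", "C")}
    # with slack 1 the A-C edge (weight 2 <= bottleneck 1 + 1) appears
    g2 = hn.build_network(steps, extra_edge_slack=1)
    assert set(map(frozenset, g2.edges)) == {
        frozenset(p) for p in [("A", "B"), ("B", "C"), ("A", "C")]
    }
    assert not g2["A"]["C"]["in_mst"]


def test_network_star_topology_from_private_mutations():
    # star: a central haplotype, each leaf separated by its private count
    ids = list("ZABCD")
    priv = {"A": 2, "B": 3, "C": 4, "D": 5}
    d = pd.DataFrame(0, index=ids, columns=ids)
    for x, nx_ in priv.items():
        d.loc["Z", x] = d.loc[x, "Z"] = nx_
        for y, ny in priv.items():
            if x != y:
                d.loc[x, y] = nx_ + ny
    g = hn.build_network(d)
    assert sorted(g.degree, key=lambda t: t[0])[-1] == ("Z", 4)
    for x, nx_ in priv.items():
        assert g["Z"][x]["weight"] == nx_


def test_network_invariant_under_sample_reordering(micro):
    steps = micro.truth.steps
    perm = list(reversed(steps.index))
    g1 = hn.build_network(steps)
    g2 = hn.build_network(steps.loc[perm, perm])
    assert nx.utils.graphs_equal(g1, g2)


def test_mst_path_respects_triangle_property(micro):
    steps = micro.truth.steps
    g = hn.build_network(steps)
    for a in steps.index:
        for b in steps.index:
            if a >= b:
                continue
            path = nx.shortest_path(g, a, b)
            w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
            assert w >= steps.loc[a, b]
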