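"""Allele encoding, UPGMA, discrimination power, minimal marker sets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from plastomarker import discrimination as dm
from plastomarker.msa_markers import MarkerLocus

from _oracles import minimal_subsets_oracle


def _marker(mid, kind, alleles):
    return MarkerLocus(mid, kind, 0, 1, alleles, len(set(alleles.values())) > 1)


def test_encode_ssr_and_indel_columns():
    m1 = _marker("ssr1", "ssr", {"a": 5, "b": 5, "c": 7})
    m2 = _marker("ind1", "indel", {"a": "------------", "b": "ACGTACGTACGT", "c": "------------"})
    mat = dm.encode([m1, m2])
    assert list(mat.numeric["ssr1"]) == [5.0, 5.0, 7.0]
    assert list(mat.numeric["ind1"]) == [0.0, 12.0, 0.0]
    # distinct categorical profiles <-> distinct numeric rows
    prof = mat.categorical.apply(tuple, axis=1)
    nums = mat.numeric.apply(tuple, axis=1)
    assert (prof.duplicated() == nums.duplicated()).all()


def test_encode_injectivity_fallback_for_equal_length_indels():
    m = _marker("ind", "indel", {"a": "AC--", "b": "GT--", "c": "AC--"})
    mat = dm.encode([m])
    assert mat.numeric["ind"]["a"] == mat.numeric["ind"]["c"]
    assert mat.numeric["ind"]["a"] != mat.numeric["ind"]["b"]


def test_upgma_hand_computed_three_points():
    d = pd.DataFrame(
        [[0, 1, 4], [1, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC"),
        dtype=float,
    )
    dend = dm.upgma(d)
    heights = [h for h, _, _ in dend.merges]
    assert heights == [0.5, 2.0]
    assert set(dend.merges[0][1] + dend.merges[0][2]) == {"A", "B"}
    assert dend.is_ultrametric()


@pytest.mark.parametrize("trial", range(10))
def test_upgma_matches_scipy_average_linkage(trial):
    rng = np.random.default_rng(3000 + trial)
    n = 8
    x = rng.random((n, 4))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(d, index=labels, columns=labels)
    dend = dm.upgma(df)
    z = linkage(squareform(d), method="average")
    ours = sorted(2 * h for h, _, _ in dend.merges)
    assert np.allclose(ours, sorted(z[:, 2]))
    coph = pd.DataFrame(
        squareform(cophenet(z)), index=labels, columns=labels
    )
    got = dend.cophenetic().loc[labels, labels]
    assert np.allclose(got.to_numpy(), coph.to_numpy())


def test_upgma_reproduces_ultrametric_input_exactly():
    # a tree-realisable ultrametric: ((A,B):1,(C,D):2):3
    d = pd.DataFrame(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )
    dend = dm.upgma(d)
    assert np.allclose(dend.cophenetic().to_numpy(), d.to_numpy())


def test_upgma_rejects_bad_matrices():
    bad = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"))
    with pytest.raises(ValueError):
        dm.upgma(bad)


def _random_matrix(rng, n_samples=6, n_markers=8):
    cats = rng.integers(0, 3, size=(n_samples, n_markers))
    samples = [f"s{i}" for i in range(n_samples)]
    markers = [f"m{j}" for j in range(n_markers)]
    cat = pd.DataFrame(cats.astype(str), index=samples, columns=markers)
    return dm.AlleleMatrix(cat, pd.DataFrame(cats.astype(float), index=samples, columns=markers))


def test_discrimination_power_groups():
    cat = pd.DataFrame(
        {"m1": ["1", "1", "2"], "m2": ["0", "0", "0"]}, index=["a", "b", "c"]
    )
    mat = dm.AlleleMatrix(cat, pd.DataFrame({"m1": [1.0, 1.0, 2.0], "m2": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]))
    assert dm.discrimination_power(mat) == [["a", "b"], ["c"]]
    assert dm.discrimination_power(mat, ["m2"]) == [["a", "b", "c"]]


def test_family_ssr_panel_groups_and_minimum(micro, micro_analysis):
    from plastomarker import msa_markers as mm

    markers = mm.call_orthologous_ssrs(micro.alignment, micro_analysis.candidates)
    poly = [m for m in markers if m.polymorphic]
    mat = dm.encode(poly)
    groups = dm.discrimination_power(mat)
    assert groups == [["bb"], ["cb"], ["lb", "nhb", "rb"], ["shb"]]
    res = dm.minimal_marker_set(mat, target=groups)
    assert res.size == 3  # one separator per resolvable species


def test_family_indel_panel_achieves_full_discrimination_with_two(micro, micro_analysis):
    mat = dm.encode(micro_analysis.indel_markers_sc)
    res = dm.minimal_marker_set(mat)
    assert res.achievable and res.size == 2


@pytest.mark.parametrize("trial", range(15))
def test_minimal_set_equals_bruteforce_oracle(trial):
    rng = np.random.default_rng(4000 + trial)
    mat = _random_matrix(rng)
    samples, markers = mat.samples, mat.markers
    groups = dm.discrimination_power(mat)
    res = dm.minimal_marker_set(mat, target=groups)
    gid = {s: i for i, g in enumerate(groups) for s in g}
    required = [
        (a, b) for a, b in itertools.combinations(samples, 2) if gid[a] != gid[b]
    ]
    profiles = {s: {m: mat.categorical.loc[s, m] for m in markers} for s in samples}
    osize, osubs = minimal_subsets_oracle(profiles, markers, required)
    assert res.size == osize
    assert sorted(res.subsets) == sorted(osubs)


def test_unachievable_target_reports_inseparable_groups():
    cat = pd.DataFrame({"m1": ["1", "1", "2"]}, index=["a", "b", "c"])
    mat = dm.AlleleMatrix(cat, pd.DataFrame({"m1": [1.0, 1.0, 2.0]}, index=["a", "b", "c"]))
    res = dm.minimal_marker_set(mat)  # all singletons unreachable
    assert not res.achievable
    assert res.inseparable == [["a", "b"]]


def test_adding_markers_only_refines_partitions(rng):
    mat = _random_matrix(rng, 6, 6)
    markers = mat.markers

    def as_sets(groups):
        return {frozenset(g) for g in groups}

    for k in range(1, len(markers)):
        before = as_sets(dm.discrimination_power(mat, markers[:k]))
        after = as_sets(dm.discrimination_power(mat, markers[: k + 1]))
        for grp in after:
            assert any(grp <= g for g in before)


def test_greedy_fallback_flagged_non_optimal(rng):
    mat = _random_matrix(rng, 5, 30)
    res = dm.minimal_marker_set(mat, exhaustive_max=10)
    groups = dm.discrimination_power(mat)
    if len(groups) == len(mat.samples):
        assert res.achievable and not res.optimal
        got = dm.discrimination_power(mat, list(res.subsets[0]))
        assert len(got) == len(mat.samples)
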