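"""Alignment-based marker calling, site classes, mutational steps."""

import numpy as np
import pandas as pd
import pytest

from plastomarker.io import AlignmentSet
from plastomarker import msa_markers as mm

from _oracles import hamming_steps_oracle


def test_classify_sites_by_definition():
    aln = AlignmentSet(
        ["a", "b", "c", "d"],
        ["AAAA", "AAAC", "AACC", "AACG"],
    )
    # columns: AAAA conserved; AAAA conserved; ACCC? let's look per column:
    # col0 AAAA conserved; col1 AAAA conserved; col2 AACC informative;
    # col3 ACCG -> two minor singletons: multi_variant_other
    sc = mm.classify_sites(aln)
    assert list(sc.classes) == [0, 0, 2, 3]
    assert sc.totals["conserved"] == 2
    assert sc.totals["parsimony_informative"] == 1
    assert sc.totals["multi_variant_other"] == 1


def test_classify_sites_singleton_and_gap_exclusion(handcount):
    sc = mm.classify_sites(handcount)
    assert sc.totals["singleton"] == 3
    assert sc.totals["parsimony_informative"] == 2
    assert sc.totals["gapped_excluded"] == 1
    assert sum(sc.totals.values()) == handcount.ncol


def test_classify_sites_partition_sums(micro):
    sc = mm.classify_sites(micro.alignment)
    assert sum(sc.totals.values()) == micro.alignment.ncol
    assert sc.snp_total == sc.totals["singleton"] + sc.totals["parsimony_informative"]


def test_classified_totals_match_planted_snps(micro):
    # 4 private SNPs per sample (24 singleton columns) and 6 shared
    # bi-allelic SNPs with both alleles in >= 2 samples (informative)
    sc = mm.classify_sites(micro.alignment)
    assert sc.totals["singleton"] == 24
    assert sc.totals["parsimony_informative"] == 6


def test_species_specific_variants_recover_private_snps(micro):
    snps = mm.species_specific_variants(micro.alignment)
    carriers = pd.Series([m.flank for m in snps]).value_counts().to_dict()
    assert carriers == {sid: 4 for sid in micro.alignment.ids}


def test_orthologous_ssr_monomorphic_group():
    aln = AlignmentSet(["a", "b"], ["CCATATATATATGG", "CCATATATATATGG"])
    from plastomarker.ssr import SSRLocus

    cands = {
        "a": [SSRLocus("a", 2, 12, "AT", 2, 5)],
        "b": [SSRLocus("b", 2, 12, "AT", 2, 5)],
    }
    (grp,) = mm.call_orthologous_ssrs(aln, cands)
    assert not grp.polymorphic and grp.alleles == {"a": 5, "b": 5}


def test_orthologous_ssrs_match_generator_truth(micro, micro_analysis):
    markers = mm.call_orthologous_ssrs(micro.alignment, micro_analysis.candidates)
    poly = {m.motif: m for m in markers if m.polymorphic}
    meta = micro.truth.ssr_meta
    exp = meta[meta.candidate & meta.polymorphic]
    assert len(poly) == len(exp)
    for lid, row in exp.iterrows():
        m = poly[row.motif]
        expected_alleles = micro.truth.ssr_alleles.loc[lid].to_dict()
        assert m.alleles == expected_alleles, lid
    # no spurious polymorphic loci: monomorphic candidates stay monomorphic
    mono_ids = meta[meta.candidate & ~meta.polymorphic].index
    got_mono = [m for m in markers if not m.polymorphic]
    assert len(got_mono) == len(mono_ids)


def test_missing_sample_in_alignment_raises(micro, micro_analysis):
    with pytest.raises(KeyError):
        mm.call_orthologous_ssrs(
            micro.alignment, {"nosuch": micro_analysis.candidates["shb"]}
        )


def test_indel_marker_trivial_two_alleles():
    aln = AlignmentSet(
        ["a", "b", "c"],
        ["AAAA------------TTTT", "AAAACCCCGGGGCCCC" + "TTTT", "AAAACCCCGGGGCCCCTTTT"],
    )
    (m,) = mm.find_indel_markers(aln, min_indel_len=3)
    assert (m.col_start, m.col_end) == (4, 16)
    assert len(set(m.alleles.values())) == 2 and m.polymorphic


def test_indel_markers_match_planted_lengths(micro, micro_analysis):
    # the planted LSC indels: alleles = gapped slices whose ungapped
    # lengths, relative to the shortest allele (a detected block excludes
    # any prefix common to all samples), equal the planted lengths
    def rel(d):
        m = min(d.values())
        return {s: v - m for s, v in d.items()}

    truth = micro.truth.indel_alleles
    detected = [
        rel({s: len(a.replace("-", "")) for s, a in m.alleles.items()})
        for m in micro_analysis.indel_markers_sc
    ]
    for iid in ("I1", "I2", "I4"):
        assert rel(truth.loc[iid].to_dict()) in detected, iid


def test_indel_flank_annotation(micro, micro_analysis):
    markers = mm.find_indel_markers(
        micro.alignment, min_indel_len=3,
        features=micro.features["shb"], feature_sample="shb",
    )
    truth = micro.truth.indel_alleles.loc["I1"].to_dict()
    i1 = next(
        m for m in markers
        if {s: len(a.replace("-", "")) for s, a in m.alleles.items()} == truth
    )
    assert i1.flank == "rpl36-rps8"
    assert len(set(i1.alleles.values())) == 5  # five in-silico alleles


def test_identity_to_consensus_forced_arithmetic():
    aln = AlignmentSet(["a", "b", "c"], ["AAAA", "AAAT", "AAAT"])
    df = mm.identity_to_consensus(aln)
    assert df.loc["a", "overall"] == pytest.approx(75.0)
    assert df.loc["b", "overall"] == pytest.approx(100.0)
    # identical rows -> 100%
    df2 = mm.identity_to_consensus(AlignmentSet(["a", "b"], ["ACGT", "ACGT"]))
    assert (df2["overall"] == 100.0).all()


def test_identity_ranks_follow_divergence(micro):
    # cb carries the most planted private changes plus the largest deletions;
    # identity to the consensus must not rank it above the least-diverged rows
    df = mm.identity_to_consensus(micro.alignment, micro.truth.region_columns)
    assert set(df.columns) == {"LSC", "IRA", "SSC", "IRB", "overall"}
    assert (df["overall"] <= 100.0).all()


def test_steps_equal_naive_oracle_and_triangle(micro):
    sub = AlignmentSet(micro.alignment.ids, [r[:10_000] for r in micro.alignment.rows])
    steps = mm.pairwise_mutational_steps(sub)
    assert steps.to_numpy().tolist() == hamming_steps_oracle(sub.rows)
    s = steps.to_numpy()
    assert (np.diag(s) == 0).all() and (s == s.T).all()
    n = len(sub.ids)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert s[i, j] <= s[i, k] + s[k, j] + 2 * 0  # Hamming triangle


def test_steps_match_generator_truth(micro):
    steps = mm.pairwise_mutational_steps(micro.alignment)
    assert steps.equals(micro.truth.steps)


def test_steps_gap_policies_differ_consistently(micro):
    pw = mm.pairwise_mutational_steps(micro.alignment, "pairwise-delete")
    ex = mm.pairwise_mutational_steps(micro.alignment, "exclude-column")
    assert (ex.to_numpy() <= pw.to_numpy()).all()
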