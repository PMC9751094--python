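"""SSR scanner semantics: thresholds, maximality, circularity, compounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from plastomarker.io import CircularSequence, revcomp
from plastomarker import ssr as ssrmod
from plastomarker.ssr import canonical_motif, find_ssrs

from _oracles import plant_ssrs, regex_ssr_oracle


def _tuples(loci):
    return sorted(
        (l.start, l.end, l.motif, l.unit_len, l.repeat_count)
        for l in loci
        if not l.compound
    )


def test_mono_run_in_flanks():
    loci = find_ssrs("GGC" + "A" * 12 + "CGT")
    assert _tuples(loci) == [(3, 15, "A", 1, 12)]


def test_threshold_boundaries():
    assert find_ssrs("G" + "A" * 9 + "G") == []          # 9 < 10 for mono
    assert len(find_ssrs("G" + "AT" * 5 + "G")) == 1     # 5 meets di threshold
    assert find_ssrs("G" + "AT" * 4 + "G") == []


def test_smallest_period_rule_and_canonical_motif():
    # an (AT)6 run is never also reported as (ATAT)3
    loci = find_ssrs("GGC" + "AT" * 6 + "CGG", thresholds={2: 5, 4: 2})
    assert len(loci) == 1 and loci[0].unit_len == 2
    assert canonical_motif("TGA") == "ATG"
    assert canonical_motif("GT", fold_strands=True) == "AC"


def test_runs_split_at_N():
    loci = find_ssrs("C" + "A" * 11 + "N" + "A" * 11 + "C")
    assert len(loci) == 1 and loci[0].compound  # two runs merged as compound
    assert len(loci[0].member_runs) == 2
    assert all(r.repeat_count == 11 for r in loci[0].member_runs)


def test_compound_merging_and_gap():
    sep = "GCTGC"  # 5 bp spacer, within the default 100 bp compound gap
    loci = find_ssrs("CC" + "A" * 10 + sep + "AT" * 6 + "CC")
    assert len(loci) == 1 and loci[0].compound
    far = "GACTGTCAGCTA" * 10  # 120 bp non-tandem spacer: two independent loci
    loci2 = find_ssrs("CC" + "A" * 10 + far + "TA" * 6 + "CC", compound_gap=100)
    assert [l.compound for l in loci2] == [False, False]


@pytest.mark.parametrize("trial", range(12))
def test_scanner_equals_regex_oracle(trial):
    rng = np.random.default_rng(2000 + trial)
    text = plant_ssrs(rng, int(rng.integers(5_000, 20_000)), 12)
    got = _tuples(find_ssrs(text, compound_gap=-(10**9)))
    assert got == regex_ssr_oracle(text)


def test_circular_scan_finds_origin_spanning_run():
    body = "CGTCTG" * 30
    s = "A" * 6 + body + "A" * 5  # A11 run across the origin
    circular = find_ssrs(CircularSequence("c", s), compound_gap=-(10**9))
    linear = find_ssrs(CircularSequence("l", s, circular=False), compound_gap=-(10**9))
    assert len(circular) >= len(linear)
    wrapped = [l for l in circular if l.end < l.start]
    assert len(wrapped) == 1
    assert wrapped[0].motif == "A" and wrapped[0].repeat_count == 11


@settings(derandomize=True, max_examples=30, deadline=None)
@given(hst.integers(0, 10**6))
def test_revcomp_invariance_of_total_count(seed):
    rng = np.random.default_rng(seed)
    text = plant_ssrs(rng, 2_000, 4)
    a = find_ssrs(text, compound_gap=-(10**9))
    b = find_ssrs(revcomp(text), compound_gap=-(10**9))
    assert len(a) == len(b)
    assert sorted(l.repeat_count for l in a) == sorted(l.repeat_count for l in b)


def test_density_arithmetic_and_pooling(micro, micro_analysis):
    from plastomarker.intervals import CircularInterval as CI
    from plastomarker.structure import RegionPartition

    part = RegionPartition(CI(0, 10_000), CI(10_000, 12_000), CI(12_000, 13_000),
                           CI(13_000, 15_000), 1.0, 15_000)
    loci = [
        ssrmod.SSRLocus("x", s, s + 10, "A", 1, 10, region="LSC") for s in (0, 50, 900)
    ]
    d = ssrmod.ssr_density(loci, part)
    assert d["LSC"] == pytest.approx(0.3)
    assert d["SC_pooled"] == pytest.approx(3 / 11.0)
    assert d["IR_pooled"] == 0.0


def test_density_matches_generator_truth(micro, micro_analysis):
    for sid, part in micro_analysis.partitions.items():
        d = micro_analysis.densities.loc[sid]
        tr = micro.truth.ssr_loci[micro.truth.ssr_loci["sample"] == sid]
        lengths = part.lengths()
        for region in ("LSC", "IRA", "SSC", "IRB"):
            expected = 1000.0 * (tr.region == region).sum() / lengths[region]
            assert d[region] == pytest.approx(expected)


def test_marker_candidate_filter_rules():
    mk = ssrmod.SSRLocus
    loci = [
        mk("x", 10, 22, "A", 1, 12, region="LSC"),                 # mono: out
        mk("x", 100, 110, "AT", 2, 5, region="IRA"),               # repeat region: out
        mk("x", 200, 210, "AT", 2, 5, region="LSC"),               # in
        mk("x", 300, 330, "compound", 0, 0, region="LSC", compound=True),  # out
        mk("x", 400, 412, "AAT", 3, 4, region="SSC"),              # in
        mk("x", 500, 512, "AAT", 3, 4, region="LSC", spans_junction=True),  # out
    ]
    kept = ssrmod.filter_marker_candidates(loci)
    assert [(l.start, l.motif) for l in kept] == [(200, "AT"), (400, "AAT")]


def test_family_ssr_loci_match_truth_exactly(micro, micro_analysis):
    for seq in micro.sequences:
        got = _tuples(micro_analysis.ssr_loci[seq.id])
        tr = micro.truth.ssr_loci[micro.truth.ssr_loci["sample"] == seq.id]
        exp = sorted(zip(tr.start, tr.end, tr.motif, tr.unit_len, tr.repeat_count))
        assert got == exp
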