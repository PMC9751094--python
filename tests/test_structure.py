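"""Quadripartite detection, IR consensus patching, junction reports."""

import numpy as np
import pytest

from plastomarker.intervals import CircularInterval as CI
from plastomarker.io import CircularSequence, revcomp
from plastomarker import structure as st

from _oracles import ir_pair_oracle


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def test_planted_ir_recovered_exactly(rng):
    lsc, ir, ssc = _rand(rng, 10_000), _rand(rng, 3_000), _rand(rng, 1_500)
    seq = CircularSequence("t", lsc + ir + ssc + revcomp(ir))
    pair = st.find_inverted_repeats(seq, min_len=500)
    part = st.partition_quadripartite(seq, pair)
    # boundaries may legitimately extend by a base when a flank pair happens
    # to match; planted flanks here are random, so allow the detector to be
    # exact or wider by at most the chance-match run at each boundary
    assert part.lengths()["SSC"] <= 1_500 and part.lengths()["IRA"] >= 3_000
    assert abs(part.lengths()["IRA"] - 3_000) <= 8
    assert part.lengths()["IRA"] == part.lengths()["IRB"]


def test_partition_tiles_genome_and_is_rotation_invariant(micro):
    for seq in micro.sequences:
        part = st.partition_quadripartite(seq, st.find_inverted_repeats(seq))
        assert sum(part.lengths().values()) == len(seq)
        rot = seq.rotate(12_345)
        part2 = st.partition_quadripartite(rot, st.find_inverted_repeats(rot))
        assert part2.lengths() == part.lengths()


def test_partition_matches_generator_truth(micro, micro_analysis):
    for sid, part in micro_analysis.partitions.items():
        assert part.lengths() == micro.truth.partitions.loc[sid].to_dict()


def test_palindromic_toy_forced_coordinates():
    seq = CircularSequence("p", "ACGCGT", circular=False)
    pair = st.find_inverted_repeats(seq, min_len=3)
    assert (pair.copy_a, pair.copy_b) == (CI(0, 3), CI(3, 6))
    assert pair.length == 3 and pair.n_mismatch == 0


def test_no_ir_returns_none(rng):
    seq = CircularSequence("r", _rand(rng, 4_000))
    assert st.find_inverted_repeats(seq, min_len=500) is None


@pytest.mark.parametrize("trial", range(8))
def test_detector_agrees_with_allpairs_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(600, 2_000))
    s = list(_rand(rng, n))
    m = int(rng.integers(60, 180))
    a = int(rng.integers(0, n // 2 - m))
    b = int(rng.integers(n // 2, n - m))
    s[b : b + m] = list(revcomp("".join(s[a : a + m])))
    text = "".join(s)
    oa, ob, olen = ir_pair_oracle(text, min_len=40)
    pair = st.find_inverted_repeats(
        CircularSequence("o", text, circular=False), min_len=40,
        max_mismatch_frac=0.0, k=11,
    )
    assert pair.length == olen
    assert (pair.copy_a.start, pair.copy_a.end) == oa
    assert (pair.copy_b.start, pair.copy_b.end) == ob


def test_consensus_patch_fixed_point(micro, micro_analysis):
    seq = micro.sequences[0]
    part = micro_analysis.partitions[seq.id]
    patched, rep = st.ir_consensus_patch(seq, part)
    assert patched.bases == seq.rotate(part.lsc.start).bases
    assert rep.substitutions == [] and rep.ira_only == [] and rep.irb_only == []


def test_consensus_patch_restores_two_base_dropout(rng):
    lsc, ira, ssc = _rand(rng, 8_000), _rand(rng, 3_000), _rand(rng, 1_200)
    irb = revcomp(ira)
    irb = irb[:1_200] + irb[1_202:]  # two bases missing from one copy
    g = lsc + ira + ssc + irb
    seq = CircularSequence("d", g)
    part = st.RegionPartition(
        CI(0, 8_000), CI(8_000, 11_000), CI(11_000, 12_200),
        CI(12_200, len(g)), 1.0, len(g),
    )
    patched, rep = st.ir_consensus_patch(seq, part)
    assert len(patched) == len(seq) + 2
    assert len(rep.ira_only) == 2 and rep.substitutions == []
    p2 = st.partition_quadripartite(
        patched, st.find_inverted_repeats(patched, min_len=500)
    )
    assert revcomp(patched.fetch(p2.ira)) == patched.fetch(p2.irb)


def test_consensus_patch_reports_planted_conflicts():
    from plastomarker.families import micro_family_config
    from plastomarker.synthetic import generate_family

    cfg = micro_family_config(5)
    cfg.asymmetric_ir_snps = [(450, 0), (520, 0), (610, 0), (700, 0), (820, 0)]
    fam = generate_family(cfg)
    seq = fam.sequences[0]
    part = st.partition_quadripartite(seq, st.find_inverted_repeats(seq))
    patched, rep = st.ir_consensus_patch(seq, part)
    assert len(rep.substitutions) == 5
    p2 = st.partition_quadripartite(patched, st.find_inverted_repeats(patched))
    assert revcomp(patched.fetch(p2.ira)) == patched.fetch(p2.irb)


def test_consensus_patch_refuses_divergent_copies(rng):
    g = _rand(rng, 2_000)
    seq = CircularSequence("bad", g)
    part = st.RegionPartition(
        CI(0, 800), CI(800, 1_200), CI(1_200, 1_600), CI(1_600, 2_000), 0.2, 2_000
    )
    with pytest.raises(ValueError, match="refusing to patch"):
        st.ir_consensus_patch(seq, part)


def test_ssc_orientation_trivial_and_family(micro, micro_analysis):
    from plastomarker.families import micro_family_config
    from plastomarker.synthetic import generate_family

    ref = micro.sequences[0]
    rp = micro_analysis.partitions[ref.id]
    assert st.classify_ssc_orientation(ref, rp, ref, rp) == "same"

    cfg = micro_family_config(5)
    cfg.ssc_flip = (False, False, False, False, False, True)
    fam = generate_family(cfg)
    parts = {
        s.id: st.partition_quadripartite(s, st.find_inverted_repeats(s))
        for s in fam.sequences
    }
    ref = fam.sequences[0]
    calls = {
        s.id: st.classify_ssc_orientation(s, parts[s.id], ref, parts[ref.id])
        for s in fam.sequences
    }
    assert calls == {"shb": "same", "rb": "same", "nhb": "same",
                     "lb": "same", "bb": "same", "cb": "inverted"}


def test_junction_report_splits_and_interior_genes(micro, micro_analysis):
    sid = "shb"
    part = micro_analysis.partitions[sid]
    jr = st.junction_gene_report(part, micro.features[sid])
    assert jr.junction_genes["LSC/IRA"] == ["psbA"]
    assert jr.gene_regions["psbA"] == {"LSC": 60, "IRA": 140}
    assert sum(jr.gene_regions["psbA"].values()) == 200
    # a gene wholly inside one region has no junction entry
    assert jr.region_assignment["rbcL"] == "LSC"
    assert all("rbcL" not in v for v in jr.junction_genes.values())
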