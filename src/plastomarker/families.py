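"""Ready-made synthetic family configurations.

``table1_family_config`` describes the package's reference study
conditions: a six-sample family of ~180-195 kb quadripartite plastomes
whose region sizes, SSR densities, marker structure and SSC inversion
emulate the six commercially relevant *Vaccinium* berry crops (southern
and northern highbush, rabbiteye and lowbush blueberry, bilberry,
cranberry). Sample ids carry the conventional role abbreviations (SHB, RB,
NHB, LB, BB, CB); every sequence is synthetic.

The marker structure is planted so the family reproduces the qualitative
discrimination findings for such a panel: ten polymorphic candidate SSR
loci that resolve only {CB}, {BB}, {SHB} against an unresolvable
{RB, NHB, LB} cluster, with three loci sufficing; and intergenic indels
(one with five alleles failing only the NHB/LB pair, flanked by
rpl36/rps8) of which a pair achieves full six-way discrimination.

``micro_family_config`` is the same architecture at toy scale (~16 kb
genomes) for oracle-checked tests.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (
    Family,
    FamilyConfig,
    GenePlan,
    IndelPlan,
    SNPPlan,
    SSRPlan,
    generate_family,
)
from .io import AlignmentSet

ROLES = ("SHB", "RB", "NHB", "LB", "BB", "CB")

_LSC_TARGET = (106385, 106427, 105714, 107607, 107134, 104591)
_IR_TARGET = (40978, 43208, 38658, 35865, 40801, 34238)
_IR_SHIFT = (0, 120, -180, 0, 60, 0)

_PC_GENES = (
    "atpA atpB atpE atpF atpH atpI ccsA cemA matK rbcL "
    "ndhA ndhB ndhC ndhD ndhE ndhF ndhG ndhH ndhI ndhJ ndhK "
    "petA petB petD petG petL petN psaA psaB psaC psaI psaJ "
    "psbA psbB psbC psbD psbE psbF psbH psbI psbJ psbK psbL psbM psbN psbT psbZ "
    "rpl2 rpl14 rpl16 rpl20 rpl22 rpl23 rpl32 rpl33 rpl36 "
    "rpoA rpoB rpoC1 rpoC2 "
    "rps2 rps3 rps4 rps7 rps8 rps11 rps12 rps14 rps15 rps16 rps18 rps19 "
    "ycf3 ycf4"
).split()
_TRNA_GENES = (
    "trnA-UGC trnC-GCA trnD-GUC trnE-UUC trnF-GAA trnfM-CAU trnG-GCC trnG-UCC "
    "trnH-GUG trnI-CAU trnI-GAU trnK-UUU trnL-CAA trnL-UAA trnL-UAG trnM-CAU "
    "trnN-GUU trnP-UGG trnP-GGG trnQ-UUG trnR-ACG trnR-CCG trnR-UCU trnS-CGA "
    "trnS-GCA trnS-GCU trnS-GGA trnS-UGA trnT-GGU trnT-UGU trnV-GAC trnV-UAC "
    "trnW-CCA trnY-GUA"
).split()
_RRNA_GENES = ("rrn16", "rrn23", "rrn4.5", "rrn5")

_PC_IR = ("rpl2", "rpl23", "ndhB", "rps7", "rps15", "ndhA", "ndhH", "ndhI",
          "ndhG", "ndhE", "ndhD")
_TRNA_IR = ("trnA-UGC", "trnI-GAU", "trnL-CAA", "trnN-GUU", "trnR-ACG", "trnV-GAC")
_INTRON_PC_LSC = ("atpF", "petB", "petD", "rpl16", "rpoC1", "rps16", "ycf3")
_INTRON_TRNA_LSC = ("trnG-UCC", "trnK-UUU", "trnL-UAA", "trnV-UAC", "trnE-UUC",
                    "trnS-CGA", "trnY-GUA")  # 19 intron genes in total: 10 + 9
_INTRON_PC_IR = ("ndhB", "rpl2")
_INTRON_TRNA_IR = ("trnA-UGC", "trnI-GAU")

assert len(_PC_GENES) == 74 and len(_TRNA_GENES) == 34


def _alloc(rng, lo, hi, items):
    """Place items (margin, width, place_fn) at non-overlapping offsets in
    [lo, hi), in random order with random slack, deterministically."""
    items = [items[i] for i in rng.permutation(len(items))]
    margins = [items[0][0]] + [
        max(items[i][0], items[i - 1][0]) for i in range(1, len(items))
    ]
    need = sum(w for _, w, _ in items) + sum(margins)
    free = (hi - lo) - need
    if free < 0:
        raise ValueError(f"layout does not fit: need {need}, have {hi - lo}")
    gaps = rng.multinomial(free, np.full(len(items) + 1, 1.0 / (len(items) + 1)))
    pos = lo
    for (m, w, fn), lead, g in zip(items, margins, gaps):
        pos += lead + int(g)
        fn(int(pos))
        pos += w


def _mk_ssr(plans, rng):
    def item(plan_proto):
        unit, counts, lid = plan_proto
        fp = len(unit) * max(counts)
        def place(pos, unit=unit, counts=counts, lid=lid):
            plans["ssr"].append((lid, pos, unit, counts))
        return (120, fp, place)
    return item


def table1_family_config(seed: int) -> FamilyConfig:
    rng = np.random.default_rng([seed, 11])
    n = 6
    lsc_len, ir_len, ssc_len = 107_800, 43_300, 3_030
    thresholds = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

    # --- polymorphic candidate SSR loci (unit >= 2, LSC): the allele table
    # resolves {CB},{BB},{SHB} and leaves {RB,NHB,LB} unresolved; one locus
    # per "separator class" is needed, so the minimal panel has size 3.
    poly = [
        ("AT", (8, 8, 8, 8, 8, 6), "pSSR01"),    # CB separator
        ("AG", (6, 6, 6, 6, 6, 9), "pSSR02"),    # CB
        ("AAT", (5, 5, 5, 5, 5, 7), "pSSR03"),   # CB
        ("AATC", (4, 4, 4, 4, 4, 3), "pSSR04"),  # CB
        ("AT", (7, 7, 7, 7, 7, 3), "pSSR05"),    # CB (allele below threshold)
        ("AC", (5, 5, 5, 5, 8, 5), "pSSR06"),    # BB
        ("ACT", (4, 4, 4, 4, 6, 4), "pSSR07"),   # BB
        ("AACG", (3, 3, 3, 3, 5, 3), "pSSR08"),  # BB
        ("AG", (9, 5, 5, 5, 5, 5), "pSSR09"),    # SHB
        ("AATG", (5, 3, 3, 3, 3, 3), "pSSR10"),  # SHB
    ]
    mono_units = ["A", "T"]
    mono_lsc = [
        (mono_units[i % 2], (10 + i % 5,) * n, f"mSSR{i + 1:02d}") for i in range(26)
    ]
    # ~30 loci per IR copy (~0.75 SSRs/kb in the repeats, twice the
    # single-copy density), mostly mononucleotide, all monomorphic
    ir_ssrs = [
        (mono_units[i % 2], (10 + i % 3,) * n, f"irSSR{i + 1:02d}") for i in range(24)
    ] + [
        ("AT", (5,) * n, "irSSR25"), ("AG", (6,) * n, "irSSR26"),
        ("AC", (5,) * n, "irSSR27"), ("AGC", (4,) * n, "irSSR28"),
        ("AAT", (4,) * n, "irSSR29"), ("AAG", (4,) * n, "irSSR30"),
    ]

    # --- indels (LSC unless noted)
    i1 = ("I1", 60, (40, 25, 10, 10, 55, 0), None)          # rpl36-rps8, 5 alleles
    i2 = ("I2", 20, (6, 6, 18, 6, 6, 6), None)              # rpoB-rpoA, resolves NHB
    i3 = ("I3", 30, (30, 30, 30, 30, 12, 30), None)         # BB-only deletion
    i4 = ("I4", 90, (0, 0, 0, 80, 0, 0),
          ("trnfM-CAU", "tRNA", 5, 72, "+"))                # CNV: extra copy in LB

    # size-tuning deltas so detected LSC lengths match the target profile;
    # split over two indels so neither alone discriminates all six samples
    ssr_delta = np.zeros(n, dtype=int)
    for unit, counts, _ in poly:
        ssr_delta += (np.array(counts) - max(counts)) * len(unit)
    indel_delta = np.zeros(n, dtype=int)
    for _, fp, lengths, _ in (i1, i2, i3, i4):
        indel_delta += np.array(lengths) - fp
    needed = (
        np.array(_LSC_TARGET) + np.array(_IR_SHIFT) - lsc_len - ssr_delta - indel_delta
    )
    a = np.zeros(n, dtype=int)
    b = np.zeros(n, dtype=int)
    A = max(needed[2], needed[3])        # NHB, LB share the sizeA allele
    a[2] = a[3] = A
    b[2], b[3] = needed[2] - A, needed[3] - A
    B = max(needed[0], needed[1])        # SHB, RB share the sizeB allele
    b[0] = b[1] = B
    a[0], a[1] = needed[0] - B, needed[1] - B
    for s in (4, 5):                     # BB, CB: split evenly
        a[s] = needed[s] // 2
        b[s] = needed[s] - a[s]
    fp_size = 2_300
    assert all(-fp_size <= v <= 0 for v in np.concatenate([a, b])), (a, b)
    size_a = ("sizeA", fp_size, tuple(int(fp_size + v) for v in a), None)
    size_b = ("sizeB", fp_size, tuple(int(fp_size + v) for v in b), None)

    border_fp = 9_500
    border_len = tuple(
        int(t - d - ir_len + border_fp) for t, d in zip(_IR_TARGET, _IR_SHIFT)
    )
    assert all(0 <= v <= border_fp for v in border_len), border_len

    # --- SNPs: 10 private per sample + 15 shared (parsimony-informative)
    snps = []
    for s, role in enumerate(ROLES):
        for i in range(10):
            groups = [0] * n
            groups[s] = 1
            snps.append((f"prv_{role}_{i + 1}", tuple(groups)))
    shared_patterns = [
        (0, 0, 1, 1, 0, 0), (1, 1, 0, 0, 0, 0), (0, 1, 1, 0, 1, 0),
        (1, 0, 0, 1, 1, 0), (0, 0, 1, 1, 1, 1), (1, 1, 1, 0, 0, 0),
        (0, 1, 0, 1, 0, 1), (1, 0, 1, 0, 1, 0), (0, 0, 0, 1, 1, 0),
        (1, 1, 0, 0, 1, 1), (0, 1, 1, 1, 0, 0), (1, 0, 0, 0, 1, 1),
        (0, 1, 0, 0, 1, 0), (1, 1, 0, 1, 0, 0), (0, 0, 1, 0, 1, 1),
    ]
    snps += [(f"shared_{i + 1}", pat) for i, pat in enumerate(shared_patterns)]

    # --- genes
    plans = {"ssr": [], "indel": [], "snp": [], "gene": []}
    exp_max = max(max(_IR_SHIFT), 0)

    def gene_item(name, kind, width, margin=60):
        strand = "+" if rng.random() < 0.5 else "-"
        def place(pos, name=name, kind=kind, width=width, strand=strand):
            plans["gene"].append(
                GenePlan(name, kind, (("lsc", pos, width, strand),))
            )
        return (margin, width, place)

    def intron_item(name, kind, widths, region="lsc", mirror=False):
        w1, intron, w2 = widths
        def place(pos, name=name, kind=kind):
            plans["gene"].append(
                GenePlan(
                    name, kind,
                    ((region, pos, w1, "+"), (region, pos + w1 + intron, w2, "+")),
                    mirror_in_irb=mirror,
                )
            )
        return (60, w1 + intron + w2, place)

    def indel_item(spec, region="lsc", flanks=None):
        iid, fp, lengths, carries = spec
        gl = gr = 0
        if flanks:
            gl, gr = flanks[0][2], flanks[1][2]
        width = gl + (30 if gl else 0) + fp + (30 if gr else 0) + gr
        def place(pos, iid=iid, fp=fp, lengths=lengths, carries=carries):
            off = pos
            if flanks:
                nameL, kindL, wl = flanks[0]
                plans["gene"].append(GenePlan(nameL, kindL, ((region, off, wl, "+"),)))
                off += wl + 30
            plans["indel"].append(IndelPlan(iid, region, off, lengths, fp, carries))
            off += fp
            if flanks:
                nameR, kindR, wr = flanks[1]
                plans["gene"].append(
                    GenePlan(nameR, kindR, ((region, off + 30, wr, "+"),))
                )
        return (80, width, place)

    def snp_item(spec, region="lsc"):
        sid, groups = spec
        def place(pos, sid=sid, groups=groups):
            plans["snp"].append(SNPPlan(sid, region, pos, groups))
        return (40, 1, place)

    ssr_item = _mk_ssr(plans, rng)

    # manual placements (reserved zones)
    plans["gene"].append(
        GenePlan("rps12", "protein_coding",
                 (("lsc", 300, 110, "+"),
                  ("lsc", 14_600, 230, "-"),
                  ("lsc", 14_950, 25, "-")))
    )
    plans["gene"].append(
        GenePlan("psbA", "protein_coding",
                 (("lsc", lsc_len - 236, 236 + 826, "+"),))
    )
    plans["gene"].append(
        GenePlan("ndhF", "protein_coding", (("ssc", 900, 1_100, "+"),))
    )

    special_lsc = {"psbA", "rps12", "ndhF", "rpl36", "rps8", "rpoB", "rpoA"}
    plain_pc = [
        g for g in _PC_GENES
        if g not in _PC_IR and g not in special_lsc and g not in _INTRON_PC_LSC
    ]
    plain_trna = [
        g for g in _TRNA_GENES if g not in _TRNA_IR and g not in _INTRON_TRNA_LSC
    ]

    lsc_items = (
        [gene_item(g, "protein_coding", int(rng.integers(240, 780))) for g in plain_pc]
        + [gene_item(g, "tRNA", 72) for g in plain_trna]
        + [intron_item(g, "protein_coding", (250, 150, 200)) for g in _INTRON_PC_LSC]
        + [intron_item(g, "tRNA", (35, 300, 38)) for g in _INTRON_TRNA_LSC]
        + [indel_item(i1, flanks=(("rpl36", "protein_coding", 110),
                                  ("rps8", "protein_coding", 130)))]
        + [indel_item(i2, flanks=(("rpoB", "protein_coding", 210),
                                  ("rpoA", "protein_coding", 190)))]
        + [indel_item(i3), indel_item(i4), indel_item(size_a), indel_item(size_b)]
        + [ssr_item(p) for p in poly + mono_lsc]
        + [snp_item(s) for s in snps]
    )
    _alloc(rng, 15_500, lsc_len - 236 - exp_max - 60, lsc_items)

    def ir_gene_item(name, kind, width):
        strand = "+" if rng.random() < 0.5 else "-"
        def place(pos, name=name, kind=kind, width=width, strand=strand):
            plans["gene"].append(
                GenePlan(name, kind, (("ir", pos, width, strand),), mirror_in_irb=True)
            )
        return (60, width, place)

    rrna_widths = {"rrn16": 1_490, "rrn23": 2_810, "rrn4.5": 103, "rrn5": 121}
    ir_items = (
        [ir_gene_item(g, "rRNA", w) for g, w in rrna_widths.items()]
        + [ir_gene_item(g, "protein_coding", int(rng.integers(300, 900)))
           for g in _PC_IR if g not in _INTRON_PC_IR]
        + [intron_item(g, "protein_coding", (300, 500, 350), region="ir", mirror=True)
           for g in _INTRON_PC_IR]
        + [ir_gene_item(g, "tRNA", 72) for g in _TRNA_IR if g not in _INTRON_TRNA_IR]
        + [intron_item(g, "tRNA", (36, 800, 37), region="ir", mirror=True)
           for g in _INTRON_TRNA_IR]
        + [indel_item(("IRborder", border_fp, border_len, None), region="ir")]
        + [ssr_item(p) for p in ir_ssrs]
    )
    _alloc(rng, 826 + 80, ir_len - 60, ir_items)

    lsc_ids = {lid for _, _, lid in poly + mono_lsc}
    return FamilyConfig(
        seed=seed,
        sample_ids=ROLES,
        lsc_len=lsc_len,
        ir_len=ir_len,
        ssc_len=ssc_len,
        ssr_plans=[
            SSRPlan(lid, "lsc" if lid in lsc_ids else "ir", pos, unit, counts)
            for lid, pos, unit, counts in plans["ssr"]
        ],
        indel_plans=plans["indel"],
        snp_plans=plans["snp"],
        gene_plans=plans["gene"],
        ir_shift=_IR_SHIFT,
        ssc_flip=(False, False, False, False, False, True),
        thresholds=thresholds,
    )


def micro_family_config(seed: int) -> FamilyConfig:
    """Toy-scale family (~16 kb genomes) with the same marker architecture."""
    rng = np.random.default_rng([seed, 13])
    n = 6
    ids = ("shb", "rb", "nhb", "lb", "bb", "cb")
    lsc_len, ir_len, ssc_len = 9_000, 3_000, 1_200
    shifts = (0, 60, -80, 0, 0, 0)

    poly = [
        ("AG", (9, 5, 5, 5, 5, 5), "pSSR1"),     # shb separator
        ("AGC", (4, 4, 4, 4, 6, 4), "pSSR2"),    # bb
        ("AAGC", (3, 3, 3, 3, 3, 5), "pSSR3"),   # cb
        ("AT", (7, 7, 7, 7, 7, 3), "pSSR4"),     # cb, below-threshold allele
    ]
    mono = [("A", (11,) * n, "mSSR1"), ("T", (12,) * n, "mSSR2")]
    plans = {"ssr": [], "indel": [], "snp": [], "gene": []}
    ssr_item = _mk_ssr(plans, rng)

    i1 = ("I1", 60, (40, 25, 10, 10, 55, 0), None)
    i2 = ("I2", 20, (6, 6, 18, 6, 6, 6), None)
    i4 = ("I4", 90, (0, 0, 0, 80, 0, 0), ("trnQ-UUG", "tRNA", 5, 72, "+"))

    snps = []
    for s, role in enumerate(ids):
        for i in range(4):
            g = [0] * n
            g[s] = 1
            snps.append((f"prv_{role}_{i + 1}", tuple(g)))
    for i, pat in enumerate(
        [(0, 0, 1, 1, 0, 0), (1, 1, 0, 0, 0, 0), (0, 1, 1, 0, 1, 0),
         (1, 0, 0, 1, 1, 0), (0, 0, 1, 1, 1, 1), (1, 1, 1, 0, 0, 0)]
    ):
        snps.append((f"shared_{i + 1}", pat))

    def gene_item(name, kind, width, margin=40):
        def place(pos, name=name, kind=kind, width=width):
            plans["gene"].append(GenePlan(name, kind, (("lsc", pos, width, "+"),)))
        return (margin, width, place)

    def indel_item(spec, region="lsc", flanks=None):
        iid, fp, lengths, carries = spec
        gl = gr = 0
        if flanks:
            gl, gr = flanks[0][2], flanks[1][2]
        width = gl + (25 if gl else 0) + fp + (25 if gr else 0) + gr
        def place(pos, iid=iid, fp=fp, lengths=lengths, carries=carries):
            off = pos
            if flanks:
                nameL, kindL, wl = flanks[0]
                plans["gene"].append(GenePlan(nameL, kindL, ((region, off, wl, "+"),)))
                off += wl + 25
            plans["indel"].append(IndelPlan(iid, region, off, lengths, fp, carries))
            off += fp
            if flanks:
                nameR, kindR, wr = flanks[1]
                plans["gene"].append(
                    GenePlan(nameR, kindR, ((region, off + 25, wr, "+"),))
                )
        return (60, width, place)

    def snp_item(spec, region="lsc"):
        sid, groups = spec
        def place(pos, sid=sid, groups=groups):
            plans["snp"].append(SNPPlan(sid, region, pos, groups))
        return (30, 1, place)

    plans["gene"].append(
        GenePlan("rps12", "protein_coding",
                 (("lsc", 300, 60, "+"), ("lsc", 700, 90, "-"), ("lsc", 850, 30, "-")))
    )
    plans["gene"].append(
        GenePlan("psbA", "protein_coding", (("lsc", lsc_len - 60, 60 + 140, "+"),))
    )
    plans["gene"].append(GenePlan("ndhF", "protein_coding", (("ssc", 100, 600, "+"),)))
    plans["gene"].append(
        GenePlan("rrn16", "rRNA", (("ir", 400, 700, "+"),), mirror_in_irb=True)
    )
    plans["gene"].append(
        GenePlan("trnA-UGC", "tRNA", (("ir", 1_250, 72, "-"),), mirror_in_irb=True)
    )

    lsc_items = (
        [gene_item("rbcL", "protein_coding", 900),
         gene_item("matK", "protein_coding", 500),
         gene_item("trnH-GUG", "tRNA", 72),
         gene_item("trnQ-UUG", "tRNA", 72)]
        + [(40, 150 + 80 + 120, _petB(plans))]
        + [indel_item(i1, flanks=(("rpl36", "protein_coding", 80),
                                  ("rps8", "protein_coding", 80)))]
        + [indel_item(i2, flanks=(("rpoB", "protein_coding", 150),
                                  ("rpoA", "protein_coding", 150)))]
        + [indel_item(i4)]
        + [ssr_item(p) for p in poly + mono]
        + [snp_item(s) for s in snps]
    )
    _alloc(rng, 1_000, lsc_len - 60 - 60 - 30, lsc_items)

    # keep IR events clear of the manual IR genes (offsets 400-1100, 1250-1322)
    ir_items = [
        (60, 400, lambda pos: plans["indel"].append(
            IndelPlan("IRborder", "ir", pos, (250, 400, 120, 30, 200, 0), 400))),
        ssr_item(("A", (10,) * n, "irSSR1")),
    ]
    _alloc(rng, 1_400, ir_len - 60, ir_items)

    ssc_items = [ssr_item(("AC", (5,) * n, "sSSR1"))]
    _alloc(rng, 750, ssc_len - 30, ssc_items)

    lsc_ids = {lid for _, _, lid in poly + mono}
    ssc_ids = {"sSSR1"}
    cfg = FamilyConfig(
        seed=seed,
        sample_ids=ids,
        lsc_len=lsc_len,
        ir_len=ir_len,
        ssc_len=ssc_len,
        ssr_plans=[
            SSRPlan(
                lid,
                "lsc" if lid in lsc_ids else ("ssc" if lid in ssc_ids else "ir"),
                pos, unit, counts,
            )
            for lid, pos, unit, counts in plans["ssr"]
        ],
        indel_plans=plans["indel"],
        snp_plans=plans["snp"],
        gene_plans=plans["gene"],
        ir_shift=shifts,
        thresholds={1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3},
    )
    return cfg


def _petB(plans):
    def place(pos):
        plans["gene"].append(
            GenePlan("petB", "protein_coding",
                     (("lsc", pos, 150, "+"), ("lsc", pos + 230, 120, "+")))
        )
    return place


def handcount_alignment() -> AlignmentSet:
    """Four-row toy alignment with exactly 3 singleton columns, 2
    parsimony-informative columns and 1 gap-excluded column, for
    hand-checkable site-classification tests."""
    rows = [
        "ACGTACGTAC",
        "ACGTACTTAG",   # col 6 T singleton; col 9 G (informative with z)
        "AGGTA-GTGC",   # col 1 G singleton; col 5 gap; col 8 G
        "ACGAACGTGG",   # col 3 A singleton; col 8 G (informative with y)
    ]
    # columns: 1,3,6 singleton; 8,9 parsimony-informative; 5 gap-excluded
    return AlignmentSet(["w", "x", "y", "z"], rows)


def table1_family(seed: int) -> Family:
    return generate_family(table1_family_config(seed))


def micro_family(seed: int) -> Family:
    return generate_family(micro_family_config(seed))


def make_fixture_suite(seed: int = 7) -> dict:
    """Curated fixtures: the Table-1-shaped six-sample family, the toy
    family for oracle tests, and a hand-countable alignment."""
    return {
        "table1": table1_family(seed),
        "micro": micro_family(seed),
        "handcount": handcount_alignment(),
    }
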