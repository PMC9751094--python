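"""Quadripartite plastome architecture.

Angiosperm plastomes are circular molecules partitioned into a large
single-copy region (LSC), a small single-copy region (SSC) and two long
inverted repeats (IRA, IRB) that are exact or near-exact reverse
complements of each other. This module detects that architecture, patches
the two IR copies to a common consensus (the standard finishing step for
draft assemblies, in which any base present in only one copy is retained
and substitution conflicts are resolved by a stated policy), classifies the
orientation of the SSC relative to a reference, and reports genes that
span region junctions.

IR detection is seed-and-extend: exact k-mer seeds between the (doubled,
for rotation invariance) sequence and its reverse complement are grouped by
diagonal, and each promising diagonal is scanned for the window maximising
matches - 3*mismatches (an X-drop-style criterion that keeps repeat
boundaries from creeping into low-identity flanks) subject to the window's
mismatch fraction staying within ``max_mismatch_frac``. The reported length
and identity describe the winning window. Detection is deterministic and,
on small inputs, checkable against a brute-force all-diagonal scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import CircularInterval
from .io import CircularSequence, GeneFeature, revcomp

REGIONS = ("LSC", "IRA", "SSC", "IRB")


@dataclass(frozen=True)
class IRPair:
    copy_a: CircularInterval  # the copy with the smaller circular start
    copy_b: CircularInterval
    length: int               # window length (per copy)
    n_mismatch: int
    identity: float


@dataclass(frozen=True)
class RegionPartition:
    lsc: CircularInterval
    ira: CircularInterval
    ssc: CircularInterval
    irb: CircularInterval
    ir_identity: float
    seq_len: int

    def interval(self, region: str) -> CircularInterval:
        return getattr(self, region.lower())

    def lengths(self) -> dict[str, int]:
        return {r: self.interval(r).length(self.seq_len) for r in REGIONS}

    def region_of(self, pos: int) -> str:
        for r in REGIONS:
            if self.interval(r).contains(pos, self.seq_len):
                return r
        raise ValueError(f"position {pos} not covered by partition")


def _byte_arrays(text: str):
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN-", b"TGCAN-"):
        comp[a] = b
    return t, comp[t][::-1].copy()


_MISMATCH_PENALTY = 3  # extension stops where local identity falls below ~75%


def _best_window(lo: int, hi: int, mm: np.ndarray, frac: float, min_len: int):
    """Best window in [lo,hi): mismatch count m must satisfy m <= frac*len,
    and the window maximises matches - penalty*mismatches (penalised so a
    low-identity flank never pays for itself, keeping boundaries stable).
    Window boundaries land on matches by construction.
    Returns (start, end, m) or None."""
    M = len(mm)
    best = None
    starts = np.concatenate(([lo], mm + 1))
    ends = np.concatenate((mm, [hi]))
    m_cap = min(M, int(frac * (hi - lo)) + 1)
    for m in range(m_cap + 1):
        s = starts[: M - m + 1]
        e = ends[m:]
        lens = e - s
        t = int(np.argmax(lens))
        ln = int(lens[t])
        if ln < min_len or m > frac * ln:
            continue
        score = ln - m - _MISMATCH_PENALTY * m
        if best is None or score > best[3]:
            best = (int(s[t]), int(e[t]), m, score)
    return best[:3] if best else None


def find_inverted_repeats(
    seq: CircularSequence,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.01,
    k: int = 21,
) -> IRPair | None:
    """Highest-scoring pair of disjoint intervals that are reverse
    complements of each other within ``max_mismatch_frac``.

    Returns ``None`` (not an exception) when no pair of at least
    ``min_len`` exists, so non-quadripartite inputs flow through.
    """
    L = len(seq)
    if L < 2 * min_len:
        return None
    k = max(4, min(k, min_len))
    T = seq.bases + seq.bases if seq.circular else seq.bases
    n = len(T)
    tb, rb = _byte_arrays(T)

    index: dict[str, list[int]] = {}
    R = T.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    for j in range(n - k + 1):
        kmer = R[j : j + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(j)
    diags: dict[int, list[int]] = {}
    for i in range(n - k + 1):
        for j in index.get(T[i : i + k], ()):
            diags.setdefault(j - i, []).append(i)

    valid = tb != ord("N")
    valid_r = valid[::-1]
    best = None  # (score, tiebreak, s, e, d, m)
    order = sorted(
        diags.items(), key=lambda kv: kv[1][-1] + k - kv[1][0], reverse=True
    )
    for d, seeds in order:
        span = seeds[-1] + k - seeds[0]
        if span < min_len:
            continue
        if best is not None and span + 1000 < best[0]:
            break
        pad = 500
        lo = max(0, seeds[0] - pad, -d)
        hi = min(n, seeds[-1] + k + pad, n - d)
        if hi - lo < min_len:
            continue
        seg = (tb[lo:hi] == rb[lo + d : hi + d]) & valid[lo:hi] & valid_r[lo + d : hi + d]
        mm = np.flatnonzero(~seg) + lo
        if (hi - lo) - len(mm) < max(min_len, best[0] if best else 0):
            continue
        win = _best_window(lo, hi, mm, max_mismatch_frac, min_len)
        if win is None:
            continue
        s, e, m = win
        # copy2 = [s,e) in T; copy1 = revcomp partner
        c1s, c1e = n - (e + d), n - (s + d)
        if c1s < e and s < c1e:  # self-overlap on this diagonal: clamp at midpoint
            e = (n - d) // 2
            if e - s < min_len:
                continue
            mm2 = mm[(mm >= s) & (mm < e)]
            win = _best_window(s, e, mm2, max_mismatch_frac, min_len)
            if win is None:
                continue
            s, e, m = win
            c1s, c1e = n - (e + d), n - (s + d)
        length = e - s
        if seq.circular:
            if 2 * length > L:
                continue
            ia = CircularInterval.from_span(c1s % L, length, L)
            ib = CircularInterval.from_span(s % L, length, L)
            if ia.overlaps(ib, L):
                continue
        else:
            if c1s < e and s < c1e:
                continue
            ia = CircularInterval(c1s, c1e, False)
            ib = CircularInterval(s, e, False)
        if ia.start > ib.start:
            ia, ib = ib, ia
        score = length - m - _MISMATCH_PENALTY * m
        key = (score, -(ia.start % L), -(ib.start % L))
        if best is None or key > (best[0], -best[1].start, -best[2].start):
            best = (score, ia, ib, length, m)
    if best is None:
        return None
    _, ia, ib, length, m = best
    return IRPair(ia, ib, length, m, 1.0 - m / length)


def partition_quadripartite(seq: CircularSequence, ir: IRPair) -> RegionPartition:
    """Label the two inter-IR segments LSC (longer) and SSC (shorter).

    Region labels are assigned purely by length, never by gene content.
    IRA is, by convention, the IR copy immediately downstream of the LSC.
    """
    L = len(seq)
    a, b = ir.copy_a, ir.copy_b
    gap1 = (b.start - a.end) % L  # after copy_a
    gap2 = (a.start - b.end) % L  # after copy_b
    if gap1 == 0 or gap2 == 0:
        raise ValueError("degenerate partition: a single-copy region has zero length")
    seg1 = CircularInterval.from_span(a.end % L, gap1, L)
    seg2 = CircularInterval.from_span(b.end % L, gap2, L)
    if gap1 >= gap2:
        lsc, ssc, ira, irb = seg1, seg2, b, a
    else:
        lsc, ssc, ira, irb = seg2, seg1, a, b
    part = RegionPartition(lsc, ira, ssc, irb, ir.identity, L)
    assert sum(part.lengths().values()) == L
    return part


@dataclass
class ConsensusReport:
    substitutions: list[tuple[int, str, str]]  # (pos in IRA, ira base, irb base) resolved
    ira_only: list[int]   # IRA positions retained though absent from IRB
    irb_only: list[int]   # consensus positions inserted from IRB
    identity: float
    consensus_length: int


def ir_consensus_patch(
    seq: CircularSequence,
    part: RegionPartition,
    conflict_policy: str = "ira",
    min_identity: float = 0.9,
) -> tuple[CircularSequence, ConsensusReport]:
    """Align the two IR copies and rebuild the genome around their consensus.

    Bases present in one copy but absent from the other are retained
    (insertion-union), so a two-base dropout in one copy lengthens the
    patched genome by two. Substitution conflicts are resolved per
    ``conflict_policy`` ("ira": keep the copy adjacent to the LSC; "irb":
    keep the other copy) and logged. The patched sequence is emitted
    rotated to start at the LSC (recorded in ``rotation_offset``).
    """
    import edlib

    L = len(seq)
    ira = seq.fetch(part.ira)
    irb_rc = revcomp(seq.fetch(part.irb))
    res = edlib.align(ira, irb_rc, mode="NW", task="path")
    dist = res["editDistance"]
    identity = 1.0 - dist / max(len(ira), len(irb_rc))
    if identity < min_identity:
        raise ValueError(
            f"IR copies of {seq.id!r} are only {identity:.1%} identical; refusing to patch"
        )
    cons, subs, a_only, b_only = [], [], [], []
    qi = ti = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch == "=":
            cons.append(ira[qi : qi + ln])
            qi += ln
            ti += ln
        elif ch == "X":
            for off in range(ln):
                a, b = ira[qi + off], irb_rc[ti + off]
                subs.append((qi + off, a, b))
                cons.append(a if conflict_policy == "ira" else b)
            qi += ln
            ti += ln
        elif ch == "I":  # bases only in IRA
            a_only.extend(range(qi, qi + ln))
            cons.append(ira[qi : qi + ln])
            qi += ln
        elif ch == "D":  # bases only in IRB
            b_only.extend(range(len("".join(cons)), len("".join(cons)) + ln))
            cons.append(irb_rc[ti : ti + ln])
            ti += ln
        else:
            raise ValueError(f"unexpected cigar op {ch!r}")
    consensus = "".join(cons)
    patched = CircularSequence(
        seq.id,
        seq.fetch(part.lsc) + consensus + seq.fetch(part.ssc) + revcomp(consensus),
        circular=seq.circular,
        rotation_offset=(seq.rotation_offset + part.lsc.start) % L,
    )
    report = ConsensusReport(subs, a_only, b_only, identity, len(consensus))
    return patched, report


def classify_ssc_orientation(
    query_seq: CircularSequence,
    query_part: RegionPartition,
    ref_seq: CircularSequence,
    ref_part: RegionPartition,
    margin: float = 0.05,
) -> str:
    """'same' / 'inverted' / 'undetermined' orientation of the query SSC
    relative to the reference SSC, by global-alignment identity with a
    safety margin (SSC orientation can be heteroplasmic in vivo)."""
    import edlib

    q = query_seq.fetch(query_part.ssc)
    r = ref_seq.fetch(ref_part.ssc)

    def ident(a, b):
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return 1.0 - d / max(len(a), len(b))

    same, inv = ident(q, r), ident(q, revcomp(r))
    if same - inv > margin:
        return "same"
    if inv - same > margin:
        return "inverted"
    return "undetermined"


@dataclass
class JunctionReport:
    junctions: dict[str, int]                      # junction name -> position (start of 2nd region)
    gene_regions: dict[str, dict[str, int]]        # gene -> region -> bp of overlap
    junction_genes: dict[str, list[str]]           # junction name -> genes spanning it
    region_assignment: dict[str, str]              # gene -> region | 'junction'


_JUNCTIONS = (("LSC", "IRA"), ("IRA", "SSC"), ("SSC", "IRB"), ("IRB", "LSC"))


def junction_gene_report(
    part: RegionPartition, features: list[GeneFeature]
) -> JunctionReport:
    """Overlap of every gene with the four regions; genes overlapping two or
    more regions are reported per junction with their split lengths (which
    sum to the gene's annotated length)."""
    L = part.seq_len
    junctions = {f"{a}/{b}": part.interval(b).start for a, b in _JUNCTIONS}
    gene_regions: dict[str, dict[str, int]] = {}
    assignment: dict[str, str] = {}
    junction_genes: dict[str, list[str]] = {j: [] for j in junctions}
    for feat in features:
        ov: dict[str, int] = {}
        for p in feat.parts:
            for r in REGIONS:
                o = p.interval.overlap_length(part.interval(r), L)
                if o:
                    ov[r] = ov.get(r, 0) + o
        total = feat.total_length(L)
        if sum(ov.values()) != total:
            raise ValueError(f"feature {feat.name!r} extends outside the sequence")
        gene_regions[feat.name] = ov
        if len(ov) == 1:
            assignment[feat.name] = next(iter(ov))
        else:
            assignment[feat.name] = "junction"
            for (a, b), jname in zip(_JUNCTIONS, junctions):
                if a in ov and b in ov:
                    # confirm the gene actually crosses this boundary point
                    jpos = junctions[jname]
                    if any(
                        p.interval.contains((jpos - 1) % L, L) for p in feat.parts
                    ) and any(p.interval.contains(jpos, L) for p in feat.parts):
                        junction_genes[jname].append(feat.name)
    return JunctionReport(junctions, gene_regions, junction_genes, assignment)
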