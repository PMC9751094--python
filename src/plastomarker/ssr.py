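"""Microsatellite (SSR) mining with MISA-style thresholds.

A simple sequence repeat is a maximal perfect tandem run of a 1-6 bp unit.
The default minimum repeat numbers follow the classic plastome screening
convention: 10 for mononucleotides, 5 for dinucleotides, 4 for
trinucleotides and 3 for tetra-/penta-/hexanucleotides. Runs of qualifying
SSRs separated by at most ``compound_gap`` bases merge into one *compound*
locus that counts once toward totals.

Conventions:

* a run is reported only at its smallest unit length (an (AT)6 run is never
  also reported as (ATAT)3);
* the reported motif is the lexicographically smallest rotation of the unit
  on the given strand (strand folding is opt-in);
* N never matches anything, so runs are split at Ns;
* the scan is circular when the sequence is: runs spanning the origin are
  found once, with a wrapping interval;
* loci are truncated to whole units, so end - start = unit_len * repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import CircularSequence, revcomp
from .structure import RegionPartition

DEFAULT_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRLocus:
    sample_id: str
    start: int           # 0-based, on the circle
    end: int             # exclusive; end < start means the locus wraps the origin
    motif: str           # canonical unit, or 'compound'
    unit_len: int        # 0 for compound loci
    repeat_count: int    # 0 for compound loci
    region: str = "unassigned"
    compound: bool = False
    member_runs: tuple = ()
    spans_junction: bool = False

    def span(self, seq_len: int) -> int:
        return (self.end - self.start) % seq_len or (self.end - self.start)


def canonical_motif(unit: str, fold_strands: bool = False) -> str:
    rots = [unit[i:] + unit[:i] for i in range(len(unit))]
    if fold_strands:
        rc = revcomp(unit)
        rots += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rots)


def _minimal_period(unit: str) -> int:
    k = len(unit)
    for p in range(1, k):
        if k % p == 0 and unit == unit[:p] * (k // p):
            return p
    return k


def _raw_runs(text: str, max_unit: int = 6):
    """Maximal perfect tandem runs (period 1..max_unit) in linear ``text``,
    as (start, span_end, unit_len); spans include trailing partial units."""
    b = np.frombuffer(text.encode(), dtype=np.uint8)
    n = len(b)
    ok = b != ord("N")
    out = []
    for k in range(1, max_unit + 1):
        if n < 2 * k:
            continue
        eq = (b[:-k] == b[k:]) & ok[:-k] & ok[k:]
        if not eq.any():
            continue
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for s, e in zip(idx[::2], idx[1::2]):
            out.append((int(s), int(e) + k, k))  # span [s, e+k)
    return out


def find_ssrs(
    seq: CircularSequence | str,
    thresholds: dict[int, int] | None = None,
    compound_gap: int = 100,
    fold_strands: bool = False,
    sample_id: str | None = None,
) -> list[SSRLocus]:
    """All qualifying SSR loci of ``seq``, sorted by start, deterministic.

    Compound loci (qualifying runs closer than ``compound_gap``) are merged
    and count as a single locus; their members are kept in ``member_runs``.
    """
    if isinstance(seq, str):
        seq = CircularSequence(sample_id or "seq", seq.upper(), circular=False)
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    sid = sample_id or seq.id
    L = len(seq)
    text = seq.bases + seq.bases if seq.circular else seq.bases

    simple: list[SSRLocus] = []
    for s, span_end, k in _raw_runs(text):
        unit = text[s : s + k]
        if _minimal_period(unit) != k:
            continue  # reported at the smaller unit length instead
        reps = (span_end - s) // k
        if reps < thresholds.get(k, 10**9):
            continue
        if seq.circular:
            if s >= L:
                continue  # duplicate image in the doubled sequence
            if s == 0 and seq.bases[-1] == text[k - 1] and seq.bases[-1] != "N":
                continue  # left-extends across the origin; found as the wrapped run
            reps = min(reps, L // k)
        end = s + k * reps
        simple.append(
            SSRLocus(sid, s, end if end <= L or not seq.circular else end - L,
                     canonical_motif(unit, fold_strands), k, reps)
        )

    # sort in linear (unwrapped) coordinates for stable merging
    simple.sort(key=lambda x: (x.start, x.unit_len))

    def lin_end(loc):
        e = loc.end if loc.end > loc.start else loc.end + L
        return e

    merged: list[SSRLocus] = []
    group: list[SSRLocus] = []
    for loc in simple:
        if group and loc.start - lin_end(group[-1]) <= compound_gap:
            group.append(loc)
        else:
            if group:
                merged.append(_emit(group, sid, L, seq.circular))
            group = [loc]
    if group:
        merged.append(_emit(group, sid, L, seq.circular))
    return merged


def _emit(group: list[SSRLocus], sid: str, L: int, circular: bool) -> SSRLocus:
    if len(group) == 1:
        return group[0]
    start = group[0].start
    end = group[-1].end
    return SSRLocus(
        sid, start, end, "compound", 0, 0, compound=True, member_runs=tuple(group)
    )


def assign_regions(
    loci: list[SSRLocus], partition: RegionPartition
) -> list[SSRLocus]:
    """Label each locus with the region containing its *start*; loci whose
    span crosses a region boundary are additionally flagged."""
    L = partition.seq_len
    out = []
    for loc in loci:
        region = partition.region_of(loc.start)
        last = (loc.start + loc.span(L) - 1) % L
        flagged = partition.region_of(last) != region
        out.append(replace(loc, region=region, spans_junction=flagged))
    return out


def ssr_density(
    loci: list[SSRLocus], partition: RegionPartition
) -> dict[str, float]:
    """SSRs per kb for each region (locus counted in the region of its
    start; compounds count once), plus pooled IR and single-copy figures."""
    lengths = partition.lengths()
    if any(v == 0 for v in lengths.values()):
        raise ValueError("zero-length region in partition")
    loci = [
        loc if loc.region != "unassigned" else None for loc in loci
    ]
    counts = {r: 0 for r in lengths}
    for loc in loci:
        if loc is None:
            raise ValueError("loci must have region labels (run assign_regions)")
        counts[loc.region] += 1
    dens = {r: 1000.0 * counts[r] / lengths[r] for r in lengths}
    ir_n, ir_l = counts["IRA"] + counts["IRB"], lengths["IRA"] + lengths["IRB"]
    sc_n, sc_l = counts["LSC"] + counts["SSC"], lengths["LSC"] + lengths["SSC"]
    dens["IR_pooled"] = 1000.0 * ir_n / ir_l
    dens["SC_pooled"] = 1000.0 * sc_n / sc_l
    return dens


def filter_marker_candidates(
    loci: list[SSRLocus], partition: RegionPartition | None = None
) -> list[SSRLocus]:
    """Marker-grade loci: simple (non-compound), unit length 2-6, lying
    wholly within a single-copy region (LSC or SSC).

    Mononucleotide runs, compound repeats and loci in the repeated regions
    are excluded -- they are hard to genotype and unsuitable for primers.
    Junction-spanning loci are excluded conservatively.
    """
    if partition is not None:
        loci = assign_regions(loci, partition)
    return [
        loc
        for loc in loci
        if not loc.compound
        and 2 <= loc.unit_len <= 6
        and loc.region in ("LSC", "SSC")
        and not loc.spans_junction
    ]
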