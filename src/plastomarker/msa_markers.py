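"""Marker discovery on a multiple sequence alignment.

This module consumes alignments, it never computes them: orthologous SSR
alleles are called by overlapping the per-sample SSR candidates in
alignment-column space; indel alleles are the gapped slices over low-
homology column blocks; SNP sites are classified into singletons (exactly
one sequence differs), parsimony-informative sites (>= 2 states, each in
>= 2 sequences) and a residual multi-variant class; and pairwise
"mutational steps" are Hamming counts between rows.

Gap handling is configurable because published pipelines rarely state it:
``exclude-column`` drops any column containing a gap (or N) from site
classification, and ``pairwise-delete`` compares each pair of rows only at
columns where both are ungapped. Those are the defaults for site
classification and step counting respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignmentSet, GeneFeature
from .ssr import SSRLocus, canonical_motif

GAP = ord("-")
NBYTE = ord("N")


def _matrix(aln: AlignmentSet) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    )


@dataclass(frozen=True)
class MarkerLocus:
    marker_id: str
    kind: str                      # ssr | indel | snp
    col_start: int                 # alignment columns, half-open
    col_end: int
    alleles: dict                  # sample -> repeat count (ssr), gapped slice (indel), base (snp)
    polymorphic: bool
    motif: str | None = None
    flank: str | None = None       # e.g. 'rpl36-rps8'
    detected: dict = field(default_factory=dict)  # ssr only: sample -> run met threshold?


@dataclass
class SiteClassification:
    classes: np.ndarray            # per-column code
    totals: dict[str, int]
    CODES = ("conserved", "singleton", "parsimony_informative", "multi_variant_other",
             "gapped_excluded")

    @property
    def snp_total(self) -> int:
        return self.totals["singleton"] + self.totals["parsimony_informative"]


def map_coord(aln: AlignmentSet, sample: str, seq_position: int) -> int:
    """Alignment column holding ungapped position ``seq_position`` of
    ``sample`` (bijective with :func:`unmap_coord` on non-gap columns)."""
    return aln.pos_to_col(sample, seq_position)


def unmap_coord(aln: AlignmentSet, sample: str, column: int) -> int:
    return aln.col_to_pos(sample, column)


def _tandem_count(slice_ungapped: str, motif: str) -> int:
    """Longest tandem run of any rotation of ``motif`` inside the slice."""
    k = len(motif)
    best = 0
    s = slice_ungapped
    for i in range(len(s)):
        unit = s[i : i + k]
        if len(unit) < k or canonical_motif(unit) != motif:
            continue
        n = 1
        while s[i + n * k : i + (n + 1) * k] == unit:
            n += 1
        best = max(best, n)
    return best


def call_orthologous_ssrs(
    aln: AlignmentSet, candidates: dict[str, list[SSRLocus]]
) -> list[MarkerLocus]:
    """Group per-sample SSR candidates into orthologous loci by overlap of
    their alignment-column intervals (union interval per group).

    The allele is the repeat count. Samples without a qualifying run at the
    locus get the count of the (threshold-failing) repeats actually present
    at the mapped interval -- possibly 0 -- and are marked undetected, so
    both "shorter allele" and "absent" encodings stay available.
    """
    for sid in candidates:
        if sid not in aln.ids:
            raise KeyError(f"sample {sid!r} not present in the alignment")
    intervals = []  # (col_start, col_end, sample, locus)
    for sid, loci in candidates.items():
        for loc in loci:
            span = loc.end - loc.start
            if span <= 0:
                continue  # wrapped loci are not comparable across a linear MSA
            c0 = aln.pos_to_col(sid, loc.start)
            c1 = aln.pos_to_col(sid, loc.end - 1) + 1
            intervals.append((c0, c1, sid, loc))
    intervals.sort(key=lambda t: (t[0], t[1]))
    groups: list[list] = []
    cur, cur_end = [], -1
    for iv in intervals:
        if cur and iv[0] < cur_end:
            cur.append(iv)
            cur_end = max(cur_end, iv[1])
        else:
            if cur:
                groups.append(cur)
            cur, cur_end = [iv], iv[1]
    if cur:
        groups.append(cur)

    out = []
    for gi, grp in enumerate(groups):
        c0 = min(iv[0] for iv in grp)
        c1 = max(iv[1] for iv in grp)
        motifs = [iv[3].motif for iv in grp]
        motif = max(sorted(set(motifs)), key=motifs.count)
        alleles, detected = {}, {}
        by_sample = {iv[2]: iv[3] for iv in grp}
        for sid in aln.ids:
            if sid in by_sample:
                alleles[sid] = by_sample[sid].repeat_count
                detected[sid] = True
            else:
                sl = aln.row(sid)[c0:c1].replace("-", "")
                alleles[sid] = _tandem_count(sl, motif)
                detected[sid] = False
        out.append(
            MarkerLocus(
                f"ssr{gi + 1}", "ssr", c0, c1, alleles,
                len(set(alleles.values())) > 1, motif=motif, detected=detected,
            )
        )
    return out


def find_indel_markers(
    aln: AlignmentSet,
    min_indel_len: int = 3,
    features: list[GeneFeature] | None = None,
    feature_sample: str | None = None,
) -> list[MarkerLocus]:
    """Maximal column blocks where at least one row carries a gap run of
    ``min_indel_len`` or more; the allele is each sample's gapped slice, so
    distinct indel lengths are distinct alleles. Blocks are annotated with
    the flanking gene names when ``features`` (in ``feature_sample``'s
    sequence coordinates) are provided."""
    mat = _matrix(aln)
    blocks: list[tuple[int, int]] = []
    for r in range(mat.shape[0]):
        isgap = mat[r] == GAP
        if not isgap.any():
            continue
        idx = np.flatnonzero(np.diff(np.concatenate(([0], isgap.view(np.int8), [0]))))
        for s, e in zip(idx[::2], idx[1::2]):
            if e - s >= min_indel_len:
                blocks.append((int(s), int(e)))
    blocks.sort()
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for bi, (s, e) in enumerate(merged):
        alleles = {sid: aln.row(sid)[s:e] for sid in aln.ids}
        flank = None
        if features is not None and feature_sample is not None:
            flank = _flank_name(aln, feature_sample, features, s, e)
        out.append(
            MarkerLocus(
                f"indel{bi + 1}", "indel", s, e, alleles,
                len(set(alleles.values())) > 1, flank=flank,
            )
        )
    return out


def _flank_name(aln, sample, features, col_s, col_e) -> str:
    m = aln._map(sample)
    p0 = int(np.searchsorted(m, col_s))          # first seq pos at/after block start
    p1 = int(np.searchsorted(m, col_e)) - 1      # last seq pos before block end
    left = right = None
    left_end = right_start = None
    for f in features:
        for part in f.parts:
            if part.interval.wraps:
                continue
            a, b = part.interval.start, part.interval.end
            if b <= p0 and (left_end is None or b > left_end):
                left, left_end = f.name, b
            if a > p1 and (right_start is None or a < right_start):
                right, right_start = f.name, a
    return f"{left or '.'}-{right or '.'}"


def classify_sites(
    aln: AlignmentSet, gap_policy: str = "exclude-column"
) -> SiteClassification:
    """Per-column site classes.

    singleton: exactly one row differs from all the others.
    parsimony-informative: >= 2 states, each present in >= 2 rows.
    A column whose two (or more) minor alleles each occur once is
    "multi_variant_other" -- it contains singletons but is not informative.
    """
    mat = _matrix(aln)
    nrow, ncol = mat.shape
    if gap_policy == "exclude-column":
        excluded = ((mat == GAP) | (mat == NBYTE)).any(axis=0)
        counts = np.stack([(mat == b).sum(axis=0) for b in b"ACGT"])
    elif gap_policy == "gap-as-state":
        excluded = (mat == NBYTE).any(axis=0)
        counts = np.stack([(mat == b).sum(axis=0) for b in b"ACGT-"])
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    present = (counts > 0).sum(axis=0)
    ge2 = (counts >= 2).sum(axis=0)
    mx = counts.max(axis=0)

    classes = np.full(ncol, 3, dtype=np.int8)  # multi_variant_other
    classes[present <= 1] = 0                  # conserved
    classes[(present == 2) & (mx == nrow - 1)] = 1   # singleton
    classes[ge2 >= 2] = 2                      # parsimony-informative
    classes[excluded] = 4
    totals = {
        name: int((classes == code).sum())
        for code, name in enumerate(SiteClassification.CODES)
    }
    return SiteClassification(classes, totals)


def identity_to_consensus(
    aln: AlignmentSet, regions: dict[str, tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Per-sample percent identity to the column-majority consensus, overall
    and per region (regions given as half-open column intervals).

    The consensus symbol is the most frequent one per column, ties broken
    lexicographically; gaps participate as symbols."""
    mat = _matrix(aln)
    symbols = np.frombuffer(b"-ACGNT", dtype=np.uint8)  # lexicographic order
    counts = np.stack([(mat == b).sum(axis=0) for b in symbols])
    consensus = symbols[counts.argmax(axis=0)]  # argmax -> first (smallest) on ties
    match = mat == consensus[None, :]
    regions = dict(regions or {})
    regions["overall"] = (0, mat.shape[1])
    data = {
        rname: 100.0 * match[:, a:b].mean(axis=1) for rname, (a, b) in regions.items()
    }
    return pd.DataFrame(data, index=aln.ids)


def species_specific_variants(aln: AlignmentSet, gap_policy: str = "exclude-column") -> list[MarkerLocus]:
    """Columns where exactly one sample carries a private base (the
    singleton columns), annotated with the carrier: candidate SNP markers."""
    mat = _matrix(aln)
    sc = classify_sites(aln, gap_policy)
    out = []
    for col in np.flatnonzero(sc.classes == 1):
        colv = mat[:, col]
        vals, cnt = np.unique(colv, return_counts=True)
        minor = vals[cnt.argmin()]
        carrier = aln.ids[int(np.flatnonzero(colv == minor)[0])]
        alleles = {sid: chr(colv[i]) for i, sid in enumerate(aln.ids)}
        out.append(
            MarkerLocus(
                f"snp@{col}", "snp", int(col), int(col) + 1, alleles, True,
                flank=carrier,
            )
        )
    return out


def pairwise_mutational_steps(
    aln: AlignmentSet, gap_policy: str = "pairwise-delete"
) -> pd.DataFrame:
    """Symmetric matrix of mutational steps: the number of columns at which
    two rows hold different non-excluded symbols (a Hamming count)."""
    mat = _matrix(aln)
    ok = (mat != GAP) & (mat != NBYTE)
    n = len(aln.ids)
    steps = np.zeros((n, n), dtype=int)
    if gap_policy == "pairwise-delete":
        for i in range(n):
            for j in range(i + 1, n):
                both = ok[i] & ok[j]
                steps[i, j] = steps[j, i] = int((both & (mat[i] != mat[j])).sum())
    elif gap_policy == "exclude-column":
        keep = ok.all(axis=0)
        sub = mat[:, keep]
        for i in range(n):
            for j in range(i + 1, n):
                steps[i, j] = steps[j, i] = int((sub[i] != sub[j]).sum())
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    return pd.DataFrame(steps, index=aln.ids, columns=aln.ids)
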