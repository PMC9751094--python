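"""Plastome I/O: FASTA sequences, gene features (GenBank / GFF3), alignments.

Coordinate conventions shared by every downstream stage:

* internal coordinates are 0-based, half-open (:class:`CircularInterval`);
* emitted GFF3 is 1-based inclusive, as the format requires;
* plastomes are circular by default and may be rotated to a shared anchor
  (the comparative convention of cutting every molecule at the same site,
  e.g. at *rbcL* for phylogenetic work).

The alphabet is strict ``{A,C,G,T,N}``. IUPAC ambiguity codes other than N
are rejected unless the caller opts in to collapsing them to N: SSR and
inverted-repeat semantics downstream are defined over ACGTN only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .intervals import CircularInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(s: str) -> str:
    """Reverse complement over the ACGTN alphabet ('-' is preserved)."""
    return s.translate(str.maketrans("ACGTN-", "TGCAN-"))[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A plastome as a circular string of bases.

    ``rotation_offset`` records how many bases the current origin is shifted
    from the original origin (positive = the sequence was rotated left).
    """

    id: str
    bases: str
    circular: bool = True
    rotation_offset: int = 0

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    def fetch(self, interval: CircularInterval) -> str:
        return "".join(self.bases[a:b] for a, b in interval.segments(len(self)))

    def rotate(self, offset: int) -> "CircularSequence":
        """Shift the origin ``offset`` bases forward (identity composed with
        the inverse rotation returns the original)."""
        if not self.circular:
            raise ValueError(f"cannot rotate non-circular sequence {self.id!r}")
        L = len(self)
        offset %= L
        return replace(
            self,
            bases=self.bases[offset:] + self.bases[:offset],
            rotation_offset=(self.rotation_offset + offset) % L,
        )

    def reverse_complement(self) -> "CircularSequence":
        return replace(self, bases=revcomp(self.bases))


@dataclass(frozen=True)
class FeaturePart:
    interval: CircularInterval
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class GeneFeature:
    """One gene (possibly multi-exon, possibly trans-spliced) on a plastome."""

    name: str
    kind: str  # protein_coding | tRNA | rRNA
    parts: tuple[FeaturePart, ...]
    sample_id: str = ""

    def __post_init__(self):
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no parts")

    @property
    def strand(self) -> str:
        return self.parts[0].strand

    def total_length(self, seq_len: int) -> int:
        return sum(p.interval.length(seq_len) for p in self.parts)


_KIND_BY_GB = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
_GB_BY_KIND = {v: k for k, v in _KIND_BY_GB.items()}


def _clean_bases(raw: str, rec_id: str, ambiguous: str) -> str:
    s = raw.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s
    bad = sorted(set(s) - _VALID)
    if ambiguous == "reject":
        raise ValueError(
            f"record {rec_id!r} contains non-ACGTN characters {bad}; "
            "pass ambiguous='collapse' to map them to N"
        )
    if ambiguous == "collapse":
        return "".join(c if c in _VALID else "N" for c in s)
    raise ValueError(f"unknown ambiguity policy {ambiguous!r}")


def read_fasta(path, circular: bool = True, ambiguous: str = "reject") -> list[CircularSequence]:
    """Read a (multi-)FASTA of plastomes.

    Duplicate record ids and empty files are hard errors; the error names
    the offending id so batch runs fail loudly.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(
            CircularSequence(rec.id, _clean_bases(str(rec.seq), rec.id, ambiguous), circular)
        )
    return out


def write_fasta(seqs, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs if isinstance(seqs, (list, tuple)) else [seqs]:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def rotate_to_anchor(seq: CircularSequence, anchor) -> CircularSequence:
    """Rotate ``seq`` so it starts at ``anchor``.

    ``anchor`` is either an integer offset or a subsequence that must occur
    exactly once over both strands. If the single occurrence is on the
    reverse strand the molecule is reverse-complemented first, so that the
    returned sequence always begins with the anchor on the forward strand.
    """
    if isinstance(anchor, int):
        return seq.rotate(anchor)
    anchor = anchor.upper()
    if len(anchor) > len(seq):
        raise ValueError("anchor longer than sequence")

    def occurrences(s: str) -> list[int]:
        hay = s + s[: len(anchor) - 1] if seq.circular else s
        hits, i = [], hay.find(anchor)
        while i != -1:
            hits.append(i)
            i = hay.find(anchor, i + 1)
        return hits

    fwd = occurrences(seq.bases)
    if len(fwd) == 1:
        # the forward strand wins; a reverse-strand hit at the complementary
        # site (palindromic anchors) is the same locus, not an ambiguity
        return seq.rotate(fwd[0])
    rc = seq.reverse_complement()
    rev = occurrences(rc.bases)
    if len(fwd) == 0 and len(rev) == 1:
        return rc.rotate(rev[0])
    raise ValueError(
        f"anchor must occur exactly once on either strand of {seq.id!r}; "
        f"found {len(fwd)} forward and {len(rev)} reverse occurrences"
    )


# ---------------------------------------------------------------------------
# features


def read_features(path, dialect: str, sample_id: str | None = None,
                  include_pseudo: bool = False) -> list[GeneFeature]:
    """Parse CDS/tRNA/rRNA features from GenBank flat files or GFF3.

    Gene names are taken with precedence gene > locus_tag > product
    (GenBank) or Name > ID (GFF3). Multi-exon structure and per-exon
    strands are preserved (needed for trans-spliced rps12). Features
    flagged as pseudogenes are dropped unless ``include_pseudo``.
    """
    if dialect == "genbank":
        return _read_genbank(path, sample_id, include_pseudo)
    if dialect == "gff3":
        return _read_gff3(path, sample_id, include_pseudo)
    raise ValueError(f"unknown feature dialect {dialect!r}")


def _read_genbank(path, sample_id, include_pseudo) -> list[GeneFeature]:
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        sid = sample_id or rec.id
        L = len(rec.seq)
        is_circular = rec.annotations.get("topology", "circular") == "circular"
        for feat in rec.features:
            kind = _KIND_BY_GB.get(feat.type)
            if kind is None:
                continue
            if not include_pseudo and "pseudo" in feat.qualifiers:
                continue
            q = feat.qualifiers
            name = (q.get("gene") or q.get("locus_tag") or q.get("product") or [None])[0]
            if name is None:
                raise ValueError(f"feature at {feat.location} in {path} has no name qualifier")
            parts = []
            for part in feat.location.parts:
                s, e = int(part.start), int(part.end)
                if e > L and not is_circular:
                    raise ValueError(
                        f"feature {name!r} extends past the end of non-circular record {sid!r}"
                    )
                parts.append(
                    FeaturePart(
                        CircularInterval.from_span(s % L, e - s, L),
                        "-" if part.strand == -1 else "+",
                    )
                )
            out.append(GeneFeature(name, kind, tuple(parts), sid))
    return out


def _read_gff3(path, sample_id, include_pseudo) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for f in db.all_features():
        kind = _KIND_BY_GB.get(f.featuretype)
        if kind is None:
            continue
        if not include_pseudo and f.attributes.get("pseudo"):
            continue
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [None])[0]
        if name is None:
            raise ValueError(f"GFF3 feature at {f.seqid}:{f.start} has no Name/ID")
        parent = (f.attributes.get("Parent") or [f"{name}@{f.start}"])[0]
        key = (f.seqid, parent)
        if key not in groups:
            groups[key] = []
            order.append(key)
        part_idx = int((f.attributes.get("part") or [len(groups[key]) + 1])[0])
        groups[key].append((part_idx, f, name, kind))
    out = []
    for key in order:
        items = sorted(groups[key], key=lambda t: t[0])
        _, first, name, kind = items[0]
        parts = tuple(
            FeaturePart(
                CircularInterval(f.start - 1, f.end, False), f.strand if f.strand in "+-" else "+"
            )
            for _, f, _, _ in items
        )
        out.append(GeneFeature(name, kind, parts, sample_id or key[0]))
    return out


def write_features(features, path, seqid: str | None = None,
                   seq_len: int | None = None) -> None:
    """Emit features as GFF3 (1-based inclusive). Multi-part features share a
    ``Parent`` attribute and carry a ``part`` index; origin-wrapping parts
    (which need ``seq_len``) are split into two lines."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, feat in enumerate(features):
            sid = seqid or feat.sample_id or "seq"
            parent = f"{feat.name}.g{i}"
            n = 0
            for part in feat.parts:
                if part.interval.wraps:
                    if seq_len is None:
                        raise ValueError(
                            f"feature {feat.name!r} wraps the origin; pass seq_len"
                        )
                    segs = part.interval.segments(seq_len)
                else:
                    segs = [(part.interval.start, part.interval.end)]
                for a, end in segs:
                    n += 1
                    fh.write(
                        "\t".join(
                            [
                                sid,
                                "plastomarker",
                                _GB_BY_KIND[feat.kind],
                                str(a + 1),
                                str(end),
                                ".",
                                part.strand,
                                ".",
                                f"ID={parent}.p{n};Parent={parent};Name={feat.name};part={n}",
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# alignments


@dataclass
class AlignmentSet:
    """Equal-length gapped rows with per-row coordinate maps."""

    ids: list[str]
    rows: list[str]
    _col_of_pos: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample ids in alignment")
        ncol = len(self.rows[0]) if self.rows else 0
        for sid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ValueError(
                    f"alignment row {sid!r} has length {len(row)}, expected {ncol}"
                )

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sample: str) -> str:
        return self.rows[self.ids.index(sample)]

    def ungapped(self, sample: str) -> str:
        return self.row(sample).replace("-", "")

    def _map(self, sample: str) -> np.ndarray:
        if sample not in self._col_of_pos:
            arr = np.frombuffer(self.row(sample).encode(), dtype=np.uint8)
            self._col_of_pos[sample] = np.flatnonzero(arr != ord("-"))
        return self._col_of_pos[sample]

    def pos_to_col(self, sample: str, pos: int) -> int:
        m = self._map(sample)
        if not 0 <= pos < len(m):
            raise IndexError(f"position {pos} outside ungapped length of {sample!r}")
        return int(m[pos])

    def col_to_pos(self, sample: str, col: int) -> int:
        """Ungapped position of a non-gap column (inverse of pos_to_col)."""
        if not 0 <= col < self.ncol:
            raise IndexError(f"column {col} out of range")
        m = self._map(sample)
        i = int(np.searchsorted(m, col))
        if i >= len(m) or m[i] != col:
            raise ValueError(f"column {col} is a gap in row {sample!r}")
        return i


def read_alignment(path, dialect: str = "fasta") -> AlignmentSet:
    fmt = {"fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    aln = AlignIO.read(str(path), fmt)
    return AlignmentSet([r.id for r in aln], [str(r.seq).upper() for r in aln])


def write_alignment(aln: AlignmentSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
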