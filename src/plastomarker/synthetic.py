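"""Synthetic plastome families with known truth.

The generator builds an ancestral quadripartite plastome
(LSC + IRA + SSC + revcomp(IRA)) and derives a family of samples by
applying *planned* edits: SSR repeat-number changes, intergenic indels,
SNPs (private or shared), a mirrored IR-internal indel and small IR
boundary shifts (expansion/contraction), and an optional SSC inversion.
Because every edit is planned, the generator can emit, alongside the
FASTA/GFF3 of each sample, the TRUE alignment (planted indels threaded as
gap columns) and truth tables for every downstream stage: per-sample SSR
loci, marker allele vectors, region partitions, and the pairwise
mutational-step matrix.

Determinism and sharpness guarantees (so planted truth is exact):

* identical seeds yield identical bytes;
* background sequence is scrubbed of any tandem span >= 8 bp (period 1-6),
  so every threshold-passing SSR is a planted one; variant neighbourhoods
  are re-validated locally with an internal mini-scanner;
* the eight base pairs flanking each IR junction are forced to mismatch
  their reverse-complement partners, so IR boundary detection cannot creep
  past the planted boundary by chance.

Orientation convention: when a sample's SSC is inverted, its FASTA carries
the inversion but the emitted true alignment keeps the SSC block in the
reference orientation (as a curated comparative alignment would), so
alignment columns stay homologous. IR edits are mirrored into both copies
unless ``asymmetric_ir_snps`` plants one-copy-only substitutions to
exercise the consensus patcher.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import CircularInterval
from .io import (
    AlignmentSet,
    CircularSequence,
    FeaturePart,
    GeneFeature,
    revcomp,
    write_alignment,
    write_fasta,
    write_features,
)
from .ssr import DEFAULT_THRESHOLDS, canonical_motif

_BASES = "ACGT"
_COMP = dict(zip("ACGT", "TGCA"))
_WALL = 8  # junction pairs forced to mismatch


# ---------------------------------------------------------------------------
# plans


@dataclass(frozen=True)
class SSRPlan:
    locus_id: str
    region: str                  # lsc | ir | ssc
    offset: int                  # ancestor coordinates within the region
    unit: str
    counts: tuple[int, ...]      # repeat number per sample

    @property
    def footprint(self) -> int:
        return len(self.unit) * max(self.counts)


@dataclass(frozen=True)
class IndelPlan:
    indel_id: str
    region: str
    offset: int
    lengths: tuple[int, ...]     # retained prefix length per sample
    footprint_len: int           # ancestor segment length (= max allele)
    carries_gene: tuple | None = None   # (name, kind, rel_offset, length, strand)

    @property
    def footprint(self) -> int:
        return self.footprint_len


@dataclass(frozen=True)
class SNPPlan:
    snp_id: str
    region: str
    offset: int
    groups: tuple[int, ...]      # allele group per sample; group 0 = ancestral

    @property
    def footprint(self) -> int:
        return 1


@dataclass(frozen=True)
class GenePlan:
    name: str
    kind: str
    parts: tuple[tuple[str, int, int, str], ...]  # (region, offset, length, strand)
    mirror_in_irb: bool = False


@dataclass
class FamilyConfig:
    seed: int
    sample_ids: tuple[str, ...]
    lsc_len: int
    ir_len: int
    ssc_len: int
    ssr_plans: list[SSRPlan] = field(default_factory=list)
    indel_plans: list[IndelPlan] = field(default_factory=list)
    snp_plans: list[SNPPlan] = field(default_factory=list)
    gene_plans: list[GenePlan] = field(default_factory=list)
    ir_shift: tuple[int, ...] = ()        # >0 expansion into LSC, <0 contraction
    ssc_flip: tuple[bool, ...] = ()
    asymmetric_ir_snps: list[tuple[int, int]] = field(default_factory=list)  # (ira offset, sample index)
    thresholds: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def __post_init__(self):
        if not self.ir_shift:
            self.ir_shift = (0,) * self.n
        if not self.ssc_flip:
            self.ssc_flip = (False,) * self.n
        for plans in (self.ssr_plans, self.indel_plans, self.snp_plans):
            for p in plans:
                per_sample = getattr(p, "counts", None) or getattr(p, "lengths", None) \
                    or getattr(p, "groups", None)
                if len(per_sample) != self.n:
                    raise ValueError(f"plan {p} does not cover all {self.n} samples")
        self._validate_layout()

    def _events(self, region: str):
        evs = [p for p in self.ssr_plans + self.indel_plans + self.snp_plans
               if p.region == region]
        evs.sort(key=lambda p: p.offset)
        return evs

    def _validate_layout(self):
        lengths = {"lsc": self.lsc_len, "ir": self.ir_len, "ssc": self.ssc_len}
        for region, rlen in lengths.items():
            prev_end = -1
            for p in self._events(region):
                if p.offset <= prev_end:
                    raise ValueError(
                        f"overlapping plan coordinates in {region}: {p} begins "
                        f"at {p.offset} before {prev_end}"
                    )
                if p.offset + p.footprint > rlen:
                    raise ValueError(f"plan {p} exceeds region {region}")
                prev_end = p.offset + p.footprint
        exp = max([d for d in self.ir_shift if d > 0], default=0)
        con = max([-d for d in self.ir_shift if d < 0], default=0)
        for p in self._events("lsc"):
            if p.offset + p.footprint > self.lsc_len - exp - _WALL:
                raise ValueError("variant plan inside the LSC expansion tail")
        for p in self._events("ir"):
            if p.offset < con + _WALL:
                raise ValueError("variant plan inside the IR contraction head")
        if any(self.ssc_flip):
            for p in self._events("ssc"):
                raise ValueError(
                    "SSC variant plans are not supported together with ssc_flip "
                    f"(found {p})"
                )


# ---------------------------------------------------------------------------
# background sequence


def _random_clean(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random ACGT with no tandem span >= 8 bp of any period 1..6."""
    arr = rng.integers(0, 4, n, dtype=np.int8)
    for _ in range(200):
        dirty = False
        for k in range(1, 7):
            if n < k + 1:
                continue
            eq = arr[:-k] == arr[k:]
            idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
            for s, e in zip(idx[::2], idx[1::2]):
                if (e - s) + k >= _WALL:
                    pos = int(s + (e - s) // 2)
                    arr[pos] = (arr[pos] + rng.integers(1, 4)) % 4
                    dirty = True
        if not dirty:
            return arr
    raise RuntimeError("background cleaning did not converge")


def _to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def _has_threshold_run(text: str, thresholds) -> bool:
    n = len(text)
    for k, tmin in thresholds.items():
        i = 0
        while i + k <= n:
            m = 0
            while i + m + k < n and text[i + m] == text[i + m + k]:
                m += 1
            if (m + k) // k >= tmin:
                return True
            i += max(1, m + 1)
    return False


def _sanitize_indel(anc: list[str], plan: "IndelPlan", rng, thresholds) -> None:
    """Ensure no truncated-allele junction of ``plan`` forms a threshold
    SSR run in any sample (the deletion may join two sub-threshold runs)."""
    off, fp = plan.offset, plan.footprint

    def junction(ln: int) -> str:
        left = "".join(anc[max(0, off - 20) : off]) + "".join(anc[off : off + ln])[-20:] \
            if ln else "".join(anc[max(0, off - 20) : off])
        right = "".join(anc[off + fp : off + fp + 20])
        return left[-20:] + right

    for _ in range(30):
        dirty = [ln for ln in set(plan.lengths) if ln < fp
                 and _has_threshold_run(junction(ln), thresholds)]
        if not dirty:
            return
        ln = dirty[0]
        pos = off + ln - 1 if ln > 0 else off - 1
        cur = anc[pos]
        anc[pos] = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4]
    raise RuntimeError(f"could not sanitize indel junctions of {plan.indel_id}")


def _fix_base(s: list[str], pos: int, forbidden: set[str], rng, thresholds) -> None:
    """Set s[pos] to a base outside ``forbidden`` that does not create a
    threshold run in the +/-14 window; deterministic order of attempts."""
    order = list(np.array(list(_BASES))[rng.permutation(4)])
    lo, hi = max(0, pos - 14), min(len(s), pos + 15)
    for b in order:
        if b in forbidden:
            continue
        s[pos] = b
        if not _has_threshold_run("".join(s[lo:hi]), thresholds):
            return
    for b in order:  # fall back: honour only the hard constraint
        if b not in forbidden:
            s[pos] = b
            return
    raise RuntimeError("no admissible base")


# ---------------------------------------------------------------------------
# generation


@dataclass
class TruthTables:
    partitions: pd.DataFrame          # samples x LSC/IRA/SSC/IRB lengths
    ssr_loci: pd.DataFrame            # one row per detected-truth locus per sample
    ssr_alleles: pd.DataFrame         # plan x sample repeat counts
    ssr_meta: pd.DataFrame            # plan: region/unit/candidate/polymorphic
    indel_alleles: pd.DataFrame       # plan x sample retained lengths
    snp_table: pd.DataFrame           # plan x sample base, + carrier
    steps: pd.DataFrame               # pairwise mutational steps (pairwise-delete)
    region_columns: dict[str, tuple[int, int]]  # alignment column blocks


@dataclass
class Family:
    config: FamilyConfig
    sequences: list[CircularSequence]
    features: dict[str, list[GeneFeature]]
    alignment: AlignmentSet
    truth: TruthTables
    ancestor: dict[str, str]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out / "family.fasta")
        for sid, feats in self.features.items():
            write_features(feats, out / f"{sid}.gff3", seqid=sid)
        write_alignment(self.alignment, out / "true_alignment.fasta")
        t = self.truth
        t.partitions.to_csv(out / "truth_partitions.csv")
        t.ssr_loci.to_csv(out / "truth_ssr_loci.csv", index=False)
        t.ssr_alleles.to_csv(out / "truth_ssr_alleles.csv")
        t.indel_alleles.to_csv(out / "truth_indel_alleles.csv")
        t.snp_table.to_csv(out / "truth_snps.csv")
        t.steps.to_csv(out / "truth_steps.csv")
        manifest = {
            "seed": self.config.seed,
            "samples": list(self.config.sample_ids),
            "lengths": {s.id: len(s) for s in self.sequences},
            "region_columns": {k: list(v) for k, v in t.region_columns.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _plan_chunk(plan, s: int, anc_text: str) -> str:
    if isinstance(plan, SSRPlan):
        return plan.unit * plan.counts[s]
    if isinstance(plan, IndelPlan):
        return anc_text[: plan.lengths[s]]
    if isinstance(plan, SNPPlan):
        return anc_text  # replaced later per group
    raise TypeError(plan)


def _build_region(cfg: FamilyConfig, region: str, anc: list[str], rng):
    """Per-sample sequence and aligned rows for one region, plus per-event
    per-sample coordinates and the per-sample region length."""
    n = cfg.n
    events = cfg._events(region)
    # pre-pass: fix SSR flanks, choose SNP alleles and sanitize indel
    # junctions so no sample acquires an unplanned threshold-passing run
    snp_bases: dict[str, dict[int, str]] = {}
    for p in events:
        if isinstance(p, SNPPlan):
            anc_base = anc[p.offset]
            bases = {0: anc_base}
            pool = [b for b in _BASES if b != anc_base]
            order = list(np.array(pool)[rng.permutation(3)])
            ctx_l = "".join(anc[max(0, p.offset - 20) : p.offset])
            ctx_r = "".join(anc[p.offset + 1 : p.offset + 21])
            for g in sorted(set(p.groups) - {0}):
                picks = order[(g - 1) % 3 :] + order[: (g - 1) % 3]
                chosen = picks[0]
                for b in picks:
                    if not _has_threshold_run(ctx_l + b + ctx_r, cfg.thresholds):
                        chosen = b
                        break
                bases[g] = chosen
            snp_bases[p.snp_id] = bases
        elif isinstance(p, SSRPlan):
            k = len(p.unit)
            left, right = p.offset - 1, p.offset + p.footprint
            if left >= 0:
                _fix_base(anc, left, {p.unit[k - 1]}, rng, cfg.thresholds)
            if right < len(anc):
                _fix_base(anc, right, {p.unit[0]}, rng, cfg.thresholds)
        elif isinstance(p, IndelPlan):
            _sanitize_indel(anc, p, rng, cfg.thresholds)

    seq_chunks = [[] for _ in range(n)]
    aln_chunks = [[] for _ in range(n)]
    coords = {}
    lens = [0] * n
    prev = 0
    for p in events:
        const = "".join(anc[prev : p.offset])
        for s in range(n):
            seq_chunks[s].append(const)
            aln_chunks[s].append(const)
            lens[s] += len(const)
        anc_text = "".join(anc[p.offset : p.offset + p.footprint])
        width = p.footprint
        pid = getattr(p, "locus_id", None) or getattr(p, "indel_id", None) or p.snp_id
        coords[pid] = []
        for s in range(n):
            if isinstance(p, SNPPlan):
                chunk = snp_bases[p.snp_id][p.groups[s]]
            else:
                chunk = _plan_chunk(p, s, anc_text)
            seq_chunks[s].append(chunk)
            aln_chunks[s].append(chunk + "-" * (width - len(chunk)))
            coords[pid].append((lens[s], lens[s] + len(chunk)))
            lens[s] += len(chunk)
        prev = p.offset + p.footprint
    tail = "".join(anc[prev:])
    for s in range(n):
        seq_chunks[s].append(tail)
        aln_chunks[s].append(tail)
        lens[s] += len(tail)
    return (
        ["".join(c) for c in seq_chunks],
        ["".join(c) for c in aln_chunks],
        coords,
        lens,
    )


def _sharpen_junctions(cfg: FamilyConfig, lsc: list[str], ira: list[str],
                       ssc: list[str], rng) -> None:
    """Force the _WALL base pairs beyond each IR junction to mismatch their
    reverse-complement partners so boundary detection is exact."""
    th = cfg.thresholds
    for t in range(_WALL):
        _fix_base(ssc, len(ssc) - 1 - t, {_COMP[ssc[t]]}, rng, th)
    deltas = sorted({max(d, 0) for d in cfg.ir_shift})
    for d in deltas:
        for t in range(_WALL):
            _fix_base(lsc, len(lsc) - d - 1 - t, {_COMP[lsc[t]]}, rng, th)
    for d in sorted({-d for d in cfg.ir_shift if d < 0}):
        for t in range(_WALL):
            pos = d - 1 - t
            if pos >= 0:
                _fix_base(ira, pos, {_COMP[lsc[t]]}, rng, th)
            else:
                _fix_base(lsc, len(lsc) + pos, {_COMP[lsc[t]]}, rng, th)


def _pairwise_steps(ids, rows) -> pd.DataFrame:
    """Independent Hamming counter (pairwise-delete over gaps and N)."""
    mats = [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
    ok = [(m != ord("-")) & (m != ord("N")) for m in mats]
    n = len(ids)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            d[i, j] = d[j, i] = int((both & (mats[i] != mats[j])).sum())
    return pd.DataFrame(d, index=list(ids), columns=list(ids))


def generate_family(cfg: FamilyConfig) -> Family:
    """Deterministically realise a family from its config."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    lsc = list(_to_str(_random_clean(rng, cfg.lsc_len)))
    ira = list(_to_str(_random_clean(rng, cfg.ir_len)))
    ssc = list(_to_str(_random_clean(rng, cfg.ssc_len)))
    _sharpen_junctions(cfg, lsc, ira, ssc, rng)

    lsc_seq, lsc_aln, lsc_coords, lsc_lens = _build_region(cfg, "lsc", lsc, rng)
    ira_seq, ira_aln, ir_coords, ira_lens = _build_region(cfg, "ir", ira, rng)
    ssc_seq, ssc_aln, ssc_coords, ssc_lens = _build_region(cfg, "ssc", ssc, rng)

    # asymmetric IRA-only substitutions (IRB keeps the ancestral base)
    irb_aln = [revcomp(row) for row in ira_aln]
    irb_seq = [revcomp(sq) for sq in ira_seq]
    for off, s in cfg.asymmetric_ir_snps:
        col = _anchored_pos(cfg, "ir", off, ir_coords, s)
        old = ira_seq[s][col]
        alt = _BASES[(_BASES.index(old) + 1) % 4]
        ira_seq[s] = ira_seq[s][:col] + alt + ira_seq[s][col + 1 :]
        acol = _aln_pos(ira_aln[s], col)
        ira_aln[s] = ira_aln[s][:acol] + alt + ira_aln[s][acol + 1 :]

    exp_max = max([d for d in cfg.ir_shift if d > 0], default=0)

    sequences, rows = [], []
    for s, sid in enumerate(cfg.sample_ids):
        d = cfg.ir_shift[s]
        irb_s = irb_seq[s][: len(irb_seq[s]) + min(d, 0)]
        tail = revcomp(lsc_seq[s][len(lsc_seq[s]) - d :]) if d > 0 else ""
        ssc_actual = revcomp(ssc_seq[s]) if cfg.ssc_flip[s] else ssc_seq[s]
        genome = lsc_seq[s] + ira_seq[s] + ssc_actual + irb_s + tail
        sequences.append(CircularSequence(sid, genome, circular=True))

        irb_row = irb_aln[s]
        if d < 0:
            irb_row = irb_row[:d] + "-" * (-d)
        tail_row = tail + "-" * (exp_max - len(tail)) if exp_max else ""
        rows.append(lsc_aln[s] + ira_aln[s] + ssc_aln[s] + irb_row + tail_row)
    alignment = AlignmentSet(list(cfg.sample_ids), rows)

    region_columns = {
        "LSC": (0, len(lsc_aln[0])),
        "IRA": (len(lsc_aln[0]), len(lsc_aln[0]) + len(ira_aln[0])),
        "SSC": (
            len(lsc_aln[0]) + len(ira_aln[0]),
            len(lsc_aln[0]) + len(ira_aln[0]) + len(ssc_aln[0]),
        ),
        "IRB": (
            len(lsc_aln[0]) + len(ira_aln[0]) + len(ssc_aln[0]),
            alignment.ncol,
        ),
    }

    features = _realise_features(cfg, lsc_coords, ir_coords, ssc_coords,
                                 lsc_lens, ira_lens, ssc_lens)

    truth = _build_truth(cfg, alignment, lsc_coords, ir_coords, ssc_coords,
                         lsc_lens, ira_lens, ssc_lens, region_columns)
    return Family(
        cfg, sequences, features, alignment, truth,
        {"lsc": "".join(lsc), "ir": "".join(ira), "ssc": "".join(ssc)},
    )


def _aln_pos(row: str, seq_pos: int) -> int:
    seen = -1
    for i, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == seq_pos:
                return i
    raise IndexError(seq_pos)


def _anchored_pos(cfg, region, anc_off, coords, s) -> int:
    """Map an ancestor offset (outside any footprint) to sample coordinates."""
    shift = 0
    for p in cfg._events(region):
        if p.offset + p.footprint <= anc_off:
            pid = getattr(p, "locus_id", None) or getattr(p, "indel_id", None) or p.snp_id
            st, en = coords[pid][s]
            shift += (en - st) - p.footprint
        elif p.offset <= anc_off:
            raise ValueError(f"ancestor offset {anc_off} lies inside footprint of {p}")
    return anc_off + shift


def _region_starts(s, lsc_lens, ira_lens, ssc_lens):
    return {
        "lsc": 0,
        "ir": lsc_lens[s],
        "ssc": lsc_lens[s] + ira_lens[s],
        "irb": lsc_lens[s] + ira_lens[s] + ssc_lens[s],
    }


def _realise_features(cfg, lsc_coords, ir_coords, ssc_coords,
                      lsc_lens, ira_lens, ssc_lens) -> dict[str, list[GeneFeature]]:
    coords = {"lsc": lsc_coords, "ir": ir_coords, "ssc": ssc_coords}
    out: dict[str, list[GeneFeature]] = {}
    for s, sid in enumerate(cfg.sample_ids):
        L = None
        starts = _region_starts(s, lsc_lens, ira_lens, ssc_lens)
        genome_len = starts["irb"] + ira_lens[s] + cfg.ir_shift[s]
        feats: list[GeneFeature] = []
        for g in cfg.gene_plans:
            parts = []
            for region, off, width, strand in g.parts:
                p0 = starts[region] + _anchored_pos(cfg, region, off, coords[region], s)
                if region == "ssc" and cfg.ssc_flip[s]:
                    rel = p0 - starts["ssc"]
                    p0 = starts["ssc"] + (ssc_lens[s] - (rel + width))
                    strand = "-" if strand == "+" else "+"
                parts.append(
                    FeaturePart(CircularInterval.from_span(p0, width, genome_len), strand)
                )
            feats.append(GeneFeature(g.name, g.kind, tuple(parts), sid))
            if g.mirror_in_irb:
                mparts = []
                for region, off, width, strand in reversed(g.parts):
                    rel = _anchored_pos(cfg, "ir", off, ir_coords, s)
                    p0 = starts["irb"] + (ira_lens[s] - (rel + width))
                    mparts.append(
                        FeaturePart(
                            CircularInterval.from_span(p0, width, genome_len),
                            "-" if strand == "+" else "+",
                        )
                    )
                feats.append(GeneFeature(g.name, g.kind, tuple(mparts), sid))
        for p in cfg.indel_plans:
            if p.carries_gene is None:
                continue
            name, kind, rel_off, width, strand = p.carries_gene
            if p.lengths[s] >= rel_off + width:
                pid = p.indel_id
                st, _ = coords[p.region][pid][s]
                p0 = starts[p.region] + st + rel_off
                feats.append(
                    GeneFeature(
                        name, kind,
                        (FeaturePart(CircularInterval.from_span(p0, width, genome_len), strand),),
                        sid,
                    )
                )
        out[sid] = feats
    return out


def _build_truth(cfg, alignment, lsc_coords, ir_coords, ssc_coords,
                 lsc_lens, ira_lens, ssc_lens, region_columns) -> TruthTables:
    n = cfg.n
    ids = list(cfg.sample_ids)
    coords = {"lsc": lsc_coords, "ir": ir_coords, "ssc": ssc_coords}

    part_rows = {}
    for s, sid in enumerate(ids):
        d = cfg.ir_shift[s]
        part_rows[sid] = {
            "LSC": lsc_lens[s] - d,
            "IRA": ira_lens[s] + d,
            "SSC": ssc_lens[s],
            "IRB": ira_lens[s] + d,
        }
    partitions = pd.DataFrame.from_dict(part_rows, orient="index")

    ssr_rows = []
    alleles = {}
    meta = {}
    for p in cfg.ssr_plans:
        k = len(p.unit)
        motif = canonical_motif(p.unit)
        region_label = {"lsc": "LSC", "ir": "IRA", "ssc": "SSC"}[p.region]
        alleles[p.locus_id] = dict(zip(ids, p.counts))
        meta[p.locus_id] = {
            "region": region_label,
            "unit_len": k,
            "motif": motif,
            "candidate": k >= 2 and p.region in ("lsc", "ssc"),
            "polymorphic": len(set(p.counts)) > 1,
        }
        for s, sid in enumerate(ids):
            if p.counts[s] < cfg.thresholds[k]:
                continue
            starts = _region_starts(s, lsc_lens, ira_lens, ssc_lens)
            st, en = coords[p.region][p.locus_id][s]
            copies = []
            if p.region == "ssc" and cfg.ssc_flip[s]:
                st, en = ssc_lens[s] - en, ssc_lens[s] - st
                copies.append(("SSC", starts["ssc"] + st, starts["ssc"] + en,
                               canonical_motif(revcomp(p.unit))))
            elif p.region == "ssc":
                copies.append(("SSC", starts["ssc"] + st, starts["ssc"] + en, motif))
            elif p.region == "lsc":
                copies.append(("LSC", st, en, motif))
            else:
                copies.append(("IRA", starts["ir"] + st, starts["ir"] + en, motif))
                copies.append(
                    ("IRB",
                     starts["irb"] + (ira_lens[s] - en),
                     starts["irb"] + (ira_lens[s] - st),
                     canonical_motif(revcomp(p.unit)))
                )
            for region, a, b, mot in copies:
                ssr_rows.append(
                    dict(locus_id=p.locus_id, sample=sid, start=a, end=b,
                         motif=mot, unit_len=k, repeat_count=p.counts[s],
                         region=region)
                )
    ssr_loci = pd.DataFrame(
        ssr_rows,
        columns=["locus_id", "sample", "start", "end", "motif", "unit_len",
                 "repeat_count", "region"],
    )
    ssr_alleles = pd.DataFrame.from_dict(alleles, orient="index")[ids] if alleles else pd.DataFrame(index=[], columns=ids)
    ssr_meta = pd.DataFrame.from_dict(meta, orient="index")

    indel_alleles = pd.DataFrame.from_dict(
        {p.indel_id: dict(zip(ids, p.lengths)) for p in cfg.indel_plans},
        orient="index",
    )
    if not indel_alleles.empty:
        indel_alleles = indel_alleles[ids]

    snp_rows = {}
    for p in cfg.snp_plans:
        counts = {g: p.groups.count(g) for g in set(p.groups)}
        private = [g for g, c in counts.items() if c == 1 and g != 0]
        carrier = ids[p.groups.index(private[0])] if len(counts) == 2 and private else None
        snp_rows[p.snp_id] = dict(zip(ids, p.groups)) | {"carrier": carrier}
    snp_table = pd.DataFrame.from_dict(snp_rows, orient="index")

    steps = _pairwise_steps(ids, alignment.rows)
    return TruthTables(partitions, ssr_loci, ssr_alleles, ssr_meta,
                       indel_alleles, snp_table, steps, region_columns)
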