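"""Cross-sample comparison of plastome gene annotations.

Counts unique functional genes per kind (protein-coding / tRNA / rRNA),
total features including IR-duplicated copies, per-gene copy numbers and
their variation across samples, region membership, and intron /
trans-splicing structure. Gene identity is by case-sensitive name with the
tRNA anticodon suffix retained (trnfM-CAU and trnM-CAU are different
isoacceptors). Duplicate counting is per annotated feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GeneFeature
from .structure import RegionPartition

KINDS = ("protein_coding", "tRNA", "rRNA")


@dataclass
class GeneInventory:
    sample_id: str
    unique_by_kind: dict[str, set[str]]
    copy_number: dict[str, int]
    intron_genes: list[str]        # >= 2 exon parts
    total_features: int

    @property
    def unique_total(self) -> int:
        return sum(len(v) for v in self.unique_by_kind.values())


def gene_inventory(features: list[GeneFeature], sample_id: str | None = None) -> GeneInventory:
    """Inventory of one sample's annotation (deterministic)."""
    if not features:
        raise ValueError("no features to inventory")
    sid = sample_id or features[0].sample_id
    unique: dict[str, set[str]] = {k: set() for k in KINDS}
    copies: dict[str, int] = {}
    introns = []
    seen_intron = set()
    for f in features:
        if not f.name:
            raise ValueError("feature without a name")
        if f.kind not in unique:
            raise ValueError(f"unknown feature kind {f.kind!r}")
        unique[f.kind].add(f.name)
        copies[f.name] = copies.get(f.name, 0) + 1
        if len(f.parts) >= 2 and f.name not in seen_intron:
            introns.append(f.name)
            seen_intron.add(f.name)
    return GeneInventory(sid, unique, copies, introns, len(features))


def copy_number_diff(inventories: dict[str, GeneInventory]) -> pd.DataFrame:
    """Genes whose copy number is not constant across samples; one row per
    varying gene, one column per sample (absent genes count 0)."""
    if len(inventories) < 2:
        raise ValueError("need at least two inventories to compare")
    genes = sorted({g for inv in inventories.values() for g in inv.copy_number})
    rows = {
        g: {sid: inv.copy_number.get(g, 0) for sid, inv in inventories.items()}
        for g in genes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[df.nunique(axis=1) > 1]


def region_membership(
    features: list[GeneFeature], partition: RegionPartition
) -> dict:
    """Genes assigned to the region containing their full span; genes that
    overlap several regions are flagged 'junction' (see
    structure.junction_gene_report for the split lengths). Also reports the
    fraction of each kind that lies in each region."""
    L = partition.seq_len
    regions = {r: [] for r in ("LSC", "IRA", "SSC", "IRB")}
    junction = []
    for f in features:
        hit = {
            r
            for p in f.parts
            for r in regions
            if p.interval.overlap_length(partition.interval(r), L) > 0
        }
        if len(hit) == 1:
            regions[next(iter(hit))].append(f)
        else:
            junction.append(f)
    fractions: dict[str, dict[str, float]] = {}
    for kind in KINDS:
        names = {f.name for f in features if f.kind == kind}
        fractions[kind] = {}
        for r, fl in regions.items():
            in_r = {f.name for f in fl if f.kind == kind}
            fractions[kind][r] = 100.0 * len(in_r) / len(names) if names else 0.0
    return {
        "regions": {r: sorted({f.name for f in fl}) for r, fl in regions.items()},
        "junction": sorted({f.name for f in junction}),
        "kind_fractions_pct": fractions,
    }


def splicing_report(
    features: list[GeneFeature],
    seq_len: int,
    trans_distance: int = 10_000,
) -> dict:
    """Intron-containing genes (>= 2 exon parts) and trans-splicing
    candidates: multi-part genes whose parts lie farther apart than
    ``trans_distance`` or sit on mixed strands (the plastid rps12
    pattern)."""
    intron: dict[str, list[str]] = {k: [] for k in KINDS}
    seen = set()
    trans = []
    for f in features:
        if len(f.parts) < 2 or f.name in seen:
            continue
        seen.add(f.name)
        intron[f.kind].append(f.name)
        strands = {p.strand for p in f.parts}
        gap = 0
        for p, q in zip(f.parts, f.parts[1:]):
            gap = max(gap, (q.interval.start - p.interval.end) % seq_len)
        if len(strands) > 1 or gap > trans_distance:
            trans.append(f.name)
    return {
        "intron_genes": {k: sorted(v) for k, v in intron.items()},
        "n_intron_genes": sum(len(v) for v in intron.values()),
        "trans_splicing_candidates": sorted(trans),
    }
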