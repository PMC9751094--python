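"""End-to-end comparative analysis of a plastome family.

Chains the stages on a set of plastomes plus a user-supplied multiple
sequence alignment: quadripartite partitioning, SSR mining and candidate
filtering, orthologous SSR / indel marker calling, site classification,
mutational steps, and discrimination analysis. Alignments are consumed,
never computed (run mafft or similar beforehand; the synthetic generator
emits its true alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import discrimination as dm
from . import msa_markers as mm
from . import ssr as ssrmod
from . import structure as st
from .io import AlignmentSet, CircularSequence


@dataclass
class FamilyAnalysis:
    partitions: dict[str, st.RegionPartition]
    ssr_loci: dict[str, list[ssrmod.SSRLocus]]
    densities: pd.DataFrame                     # samples x region SSRs/kb
    candidates: dict[str, list[ssrmod.SSRLocus]]
    ssr_markers: list[mm.MarkerLocus]
    indel_markers: list[mm.MarkerLocus]         # all blocks
    indel_markers_sc: list[mm.MarkerLocus]      # restricted to single-copy columns
    site_classes: mm.SiteClassification
    steps: pd.DataFrame
    region_columns: dict[str, tuple[int, int]]


def region_columns_from_partition(
    aln: AlignmentSet, part: st.RegionPartition, sample: str
) -> dict[str, tuple[int, int]]:
    """Map a reference sample's region intervals to alignment columns.

    Assumes the rotation convention that every molecule starts at the LSC,
    so regions are contiguous in the alignment.
    """
    out = {}
    for r in st.REGIONS:
        iv = part.interval(r)
        if iv.wraps:
            raise ValueError(f"region {r} wraps the origin; rotate to LSC first")
        c0 = aln.pos_to_col(sample, iv.start)
        c1 = aln.pos_to_col(sample, iv.end - 1) + 1
        out[r] = (c0, c1)
    return out


def analyze_family(
    sequences: list[CircularSequence],
    alignment: AlignmentSet,
    min_ir_len: int = 1000,
    max_mismatch_frac: float = 0.01,
    min_indel_len: int = 3,
    features: dict[str, list] | None = None,
    flank_sample: str | None = None,
    region_columns: dict[str, tuple[int, int]] | None = None,
) -> FamilyAnalysis:
    partitions, loci_by, cands, dens_rows = {}, {}, {}, {}
    for seq in sequences:
        pair = st.find_inverted_repeats(seq, min_ir_len, max_mismatch_frac)
        if pair is None:
            raise ValueError(f"no inverted repeat found in {seq.id!r}")
        part = st.partition_quadripartite(seq, pair)
        partitions[seq.id] = part
        loci = ssrmod.assign_regions(ssrmod.find_ssrs(seq), part)
        loci_by[seq.id] = loci
        dens_rows[seq.id] = ssrmod.ssr_density(loci, part)
        cands[seq.id] = ssrmod.filter_marker_candidates(loci)
    densities = pd.DataFrame.from_dict(dens_rows, orient="index")

    if region_columns is None:
        ref = sequences[0].id
        region_columns = region_columns_from_partition(
            alignment, partitions[ref], ref
        )
    ssr_markers = mm.call_orthologous_ssrs(alignment, cands)
    feats = (features or {}).get(flank_sample) if flank_sample else None
    indel_markers = mm.find_indel_markers(
        alignment, min_indel_len, features=feats, feature_sample=flank_sample
    )
    sc_spans = [region_columns["LSC"], region_columns["SSC"]]
    indel_sc = [
        m
        for m in indel_markers
        if any(a <= m.col_start and m.col_end <= b for a, b in sc_spans)
    ]
    site_classes = mm.classify_sites(alignment)
    steps = mm.pairwise_mutational_steps(alignment)
    return FamilyAnalysis(
        partitions, loci_by, densities, cands, ssr_markers, indel_markers,
        indel_sc, site_classes, steps, region_columns,
    )
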