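"""Mine microsatellites (SSRs) with MISA-style thresholds.

Reports per-region densities and filters the loci down to marker-grade
candidates: simple di- to hexanucleotide repeats in single-copy regions,
the class that is practical to genotype with flanking primers.
"""

from plastomarker import (
    assign_regions,
    filter_marker_candidates,
    find_inverted_repeats,
    find_ssrs,
    partition_quadripartite,
    ssr_density,
)
from plastomarker.families import micro_family

fam = micro_family(seed=5)
for seq in fam.sequences:
    part = partition_quadripartite(seq, find_inverted_repeats(seq))
    loci = assign_regions(find_ssrs(seq), part)
    dens = ssr_density(loci, part)
    cands = filter_marker_candidates(loci)
    print(f"{seq.id:5} {len(loci):3} SSRs | IR {dens['IR_pooled']:.2f}/kb, "
          f"single-copy {dens['SC_pooled']:.2f}/kb | {len(cands)} marker candidates")

print("\nMononucleotide and compound repeats, and anything inside the inverted")
print("repeats, are excluded from the candidate list: they are unreliable to")
print("genotype and their flanks are duplicated in the genome.")
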