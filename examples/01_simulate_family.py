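"""Generate a synthetic plastome family with known truth.

The generator plants every source of variation (SSR repeat changes,
indels, SNPs, IR size changes, one inverted SSC) so downstream stages can
be checked against exact expectations. The 'table1' profile mirrors the
region-size profile of six commercial berry-crop plastomes.
"""

from plastomarker.families import table1_family

fam = table1_family(seed=7)

print("sample   genome   LSC     IRA    SSC   IRB")
for seq in fam.sequences:
    p = fam.truth.partitions.loc[seq.id]
    print(f"{seq.id:6} {len(seq):8,} {p.LSC:7,} {p.IRA:6,} {p.SSC:5,} {p.IRB:6,}")

meta = fam.truth.ssr_meta
print(f"\nplanted SSR loci: {len(meta)} "
      f"({int((meta.candidate & meta.polymorphic).sum())} polymorphic marker candidates)")
print(f"planted indels:   {len(fam.truth.indel_alleles)}")
print("\nEach genome is a circular LSC+IRA+SSC+IRB molecule; the truth tables")
print("(partitions, SSR/indel/SNP alleles, step matrix) are what the pipeline")
print("must recover from the sequences alone.")
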