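# plastomarker

Comparative analysis of chloroplast genomes (plastomes) for molecular
marker discovery, aimed at species identification of closely related
crops — the motivating case being the commercial *Vaccinium* berries
(highbush/rabbiteye/lowbush blueberry, bilberry, cranberry), whose
products are prone to adulteration and mislabelling.

Angiosperm plastomes are circular molecules of 100–220 kb with a
quadripartite layout: a large and a small single-copy region (LSC, SSC)
separated by two reverse-complementary inverted repeats (IRA, IRB). The
package implements the full in-silico marker workflow on such genomes:

* **Structure** — seed-and-extend detection of the IR pair (exact k-mer
  seeds between the doubled sequence and its reverse complement, chained
  per diagonal, extended under a mismatch-penalised score), quadripartite
  partitioning, IR consensus patching for draft assemblies (bases present
  in one copy only are retained; substitution conflicts are resolved
  IRA-wins and logged), SSC orientation classification, and reports of
  genes spanning region junctions (the plastid *psbA* pattern).
* **SSRs** — MISA-style mining of perfect microsatellites with the
  classic plastome thresholds (≥10 mono-, ≥5 di-, ≥4 tri-, ≥3
  tetra/penta/hexanucleotide repeats), compound-locus merging, circular
  scanning across the origin, per-region densities, and filtering down to
  marker-grade candidates (simple 2–6 bp units in single-copy regions).
* **Alignment markers** — on a user-supplied multiple sequence alignment:
  orthologous SSR allele calling (allele = repeat number, with
  below-threshold runs re-measured rather than dropped), indel-region
  alleles with flanking-gene naming (e.g. `rpl36-rps8`), site
  classification (singletons vs parsimony-informative sites), consensus
  identity, species-specific SNPs, and pairwise mutational steps.
* **Discrimination** — categorical identity grouping, exhaustive minimal
  marker-set search (with a greedy fallback for large panels), and UPGMA
  dendrograms on Euclidean-encoded alleles (merge height = distance/2).
* **Haplotype network** — a minimum-spanning network over mutational
  steps with deterministic tie-breaks.
* **Synthetic families** — a generator that builds plastome families from
  an ancestral genome plus *planted* SNPs, SSR repeat changes, indels, IR
  expansion/contraction and SSC inversion, emitting FASTA, GFF3, the true
  alignment and exact truth tables. Every pipeline stage is tested by
  closure against these truths and against independent brute-force
  oracles.

## Worked example

```bash
python examples/04_markers_and_discrimination.py
```

```
polymorphic orthologous SSR loci: 4
  ssr1 (AT): {'shb': 7, 'rb': 7, 'nhb': 7, 'lb': 7, 'bb': 7, 'cb': 3}
  ssr2 (AG): {'shb': 9, 'rb': 5, 'nhb': 5, 'lb': 5, 'bb': 5, 'cb': 5}
  ssr3 (AGC): {'shb': 4, 'rb': 4, 'nhb': 4, 'lb': 4, 'bb': 6, 'cb': 4}
  ssr4 (AAGC): {'shb': 3, 'rb': 3, 'nhb': 3, 'lb': 3, 'bb': 3, 'cb': 5}

SSR identity groups: [['bb'], ['cb'], ['lb', 'nhb', 'rb'], ['shb']]
minimal SSR panel reaching that resolution: 3 loci (2 equivalent panels)
minimal single-copy indel panel for FULL discrimination: 2
```

The six synthetic samples play the roles of the six berry crops. Each
SSR marker's allele is its repeat number per sample (`cb: 3` at `ssr1`
is a run too short to pass the detection threshold, scored as a short
allele rather than missing). The SSR panel can isolate bilberry-,
cranberry- and southern-highbush-like samples but cannot split the
rabbiteye/northern-highbush/lowbush cluster, and three well-chosen loci
already achieve that ceiling; two intergenic indel markers suffice for
full six-way discrimination.

Other entry points: `examples/01`–`05` cover simulation, structure
detection and IR patching, SSR mining, and haplotype networks. A thin
CLI (`plastomarker structure|ssr|markers|network|simulate|convert`)
wraps the same functions for shell use.

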