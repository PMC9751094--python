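# Methods

## The problem and the model

Plastomes of closely related crop species are nearly identical in gene
content and synteny; the usable signal for identification is confined to
a handful of variation classes: microsatellite (SSR) repeat-number
changes, intergenic indels, SNPs, expansion/contraction of the inverted
repeats, and occasional inversion of the small single-copy region. The
package treats a plastome as a circular string with a quadripartite
partition LSC + IRA + SSC + IRB (labels assigned purely by length:
the longer single-copy segment is the LSC) and implements marker
discovery over a *given* multiple sequence alignment — alignments are
consumed, never computed, which removes third-party aligner variance
from everything downstream.

Internal coordinates are 0-based half-open; circular intervals carry a
`wraps` flag rather than sentinel coordinates; emitted GFF3 and TSV are
1-based inclusive. The alphabet is strict ACGTN: other IUPAC codes are
rejected unless explicitly collapsed to N, because SSR and IR semantics
are defined over ACGTN only.

## Inverted-repeat detection

Seed-and-extend: exact k-mer seeds (default k = 21) between the doubled
sequence (for rotation invariance) and its reverse complement are
grouped by diagonal; each promising diagonal is scanned for the window
maximising `matches − 3·mismatches`, subject to the window's mismatch
fraction staying within `max_mismatch_frac` (default 0.01) and length ≥
`min_len` (default 1000 bp — plastome IRs are ≥ 10 kb in practice, so
the default is conservative). The penalised score is an X-drop-style
criterion: a pure matched-length objective under a global mismatch
budget would creep hundreds of bases into random flanks (a quarter of
flank positions match by chance), whereas with penalty 3 an extension
pays only where local identity exceeds ~75%. Reported length, mismatch
count and identity describe the winning window. Detection is ungapped by
design; a copy with an internal indel is reported as the longest
consistent block (the consensus patcher, which aligns the two annotated
copies with edlib, is the indel-aware step). Self-palindromic diagonals
are clamped at their midpoint so the two copies stay disjoint. Absence
of an IR yields `None`, not an exception, so non-quadripartite inputs
flow through. On small inputs the detector is verified against an
all-diagonal brute-force scan.

## IR consensus patching

Draft assemblies routinely have unequal IR copies. `ir_consensus_patch`
globally aligns IRA against revcomp(IRB) (edlib, exact edit-distance
path), refuses to act below 90% identity, and rebuilds the genome as
LSC + consensus + SSC + revcomp(consensus), rotated to start at the LSC
(recorded in `rotation_offset`). Bases present in one copy and absent
from the other are retained (insertion-union): a two-base dropout in one
copy therefore lengthens the patched genome by two. Substitution
conflicts cannot be majority-voted with only two copies, so the copy
adjacent to the LSC wins ("IRA-wins"), and every conflict is logged with
position and both bases.

## SSC orientation

Classified by alignment identity of the query SSC against the reference
SSC versus its reverse complement, with a 5-percentage-point margin;
anything closer is "undetermined", since both SSC orientations can
coexist within an individual (heteroplasmy) and a hard call would
overstate the evidence.

## SSR mining

Maximal perfect tandem runs of 1–6 bp units, thresholds {1:10, 2:5, 3:4,
4:3, 5:3, 6:3}. A run is reported only at its smallest unit length; the
motif is the lexicographically smallest rotation on the given strand
(strand folding is opt-in); N never matches, so runs split at Ns; runs
are truncated to whole units so `end − start = unit_len · repeats`.
Circular scanning works on the doubled sequence with duplicate-image and
origin-extension filtering, so a run spanning the origin is found once
with a wrapping interval. Qualifying runs separated by ≤ `compound_gap`
(default 100 bp, the MISA convention) merge into one compound locus that
counts once toward totals. Marker candidates are simple loci with unit
length 2–6 lying wholly inside a single-copy region; junction-spanning
loci are excluded conservatively. The scanner is validated against an
independent regex-based enumerator on planted-run sequences.

## Alignment markers

* **Orthologous SSRs**: per-sample candidates are mapped to alignment
  columns and grouped by interval overlap (union interval per group).
  The allele is the repeat count; a sample without a qualifying run gets
  the count of the threshold-failing repeats actually present at the
  mapped interval (possibly 0) and is flagged undetected, so both the
  "shorter allele" and the "absent" encodings remain available — the
  choice between them is genuinely open and both are emitted.
* **Indel markers**: maximal column blocks where ≥ 1 row carries a gap
  run of ≥ `min_indel_len` (default 3). The allele is the row's gapped
  slice, so distinct indel lengths are distinct alleles; a block
  necessarily excludes any prefix shared by all samples, so allele
  lengths are meaningful relative to the shortest allele. Blocks are
  named by the nearest flanking genes when an annotation is supplied.
* **Site classes**: a column is a *singleton* when exactly one row
  differs from all others, *parsimony-informative* when ≥ 2 states each
  occur in ≥ 2 rows; a variable column that is neither (two minor
  alleles each seen once) is `multi_variant_other` — it contains
  singleton mutations but is deliberately not double-counted. Columns
  with ≥ 3 states count as one SNP site (site-based counting).
* **Gap policies** (unstated in most published pipelines, so explicit
  here): site classification defaults to `exclude-column` (any gap or N
  removes the column); mutational steps default to `pairwise-delete`
  (each pair compared over columns where both are ungapped);
  `exclude-column` steps are also available and are never larger.
  Consensus identity uses per-column majority symbols with
  lexicographic tie-breaks, gaps participating as symbols.

## Discrimination

Discrimination is categorical: samples are separated by a marker iff
their allele profiles differ; numeric encodings (SSR repeat count, indel
allele length with a category-code fallback when lengths collide, SNP
category codes) exist only for Euclidean distance matrices and UPGMA.
The UPGMA implementation is size-weighted average linkage with merge
height = inter-cluster distance / 2 (molecular-clock convention,
annotated in the output) and deterministic lexicographic tie-breaks; it
is tested against scipy's average linkage and reproduces ultrametric
inputs exactly. A marker subset *achieves* a target partition when its
induced identity partition refines the target; the minimal-set search is
exhaustive in increasing subset size up to 25 markers (all minimum-size
subsets are returned) with a greedy set-cover fallback flagged
non-optimal. Missing alleles form their own category by default
(distinguishing); a wildcard mode is available for conservative
identification claims.

## Haplotype network

A minimum-spanning network over the integer step matrix: Kruskal's MST
with lexicographic tie-breaks, plus, at positive slack, any non-tree
edge within the slack of the bottleneck (heaviest) edge on the MST path
between its endpoints. Statistical-parsimony connection limits and
median vertices are intentionally out of scope: the verifiable content
of such figures is the step counts, not the topology heuristics.

## The synthetic-data generator

The generator is first-class, tested code: it builds an ancestral
LSC + IRA + SSC + revcomp(IRA) genome and applies planned edits per
sample. Design choices that make the truth *exact* rather than
approximate:

* background sequence is scrubbed of any tandem span ≥ 8 bp (period
  1–6), so every threshold-passing SSR is planted; SSR flanks, SNP
  alleles and indel junction points are additionally validated with a
  local mini-scanner (independent of the production scanner) and
  adjusted until no unplanned threshold run can arise in any sample;
* the eight base pairs beyond each IR junction are forced to mismatch
  their reverse-complement partners, so IR boundary detection cannot
  extend past the planted boundary by a chance flank match;
* IR edits are mirrored into both copies (an `asymmetric_ir_snps` mode
  plants one-copy-only substitutions to exercise the consensus
  patcher); IR expansion duplicates the adjacent LSC tail, contraction
  trims one copy, both expressed as end-blocks in the true alignment;
* SSR mutation is direct repeat-count assignment per sample, not a
  stochastic slippage model — marker *calling* is under test, not
  microsatellite evolution;
* the true alignment threads planted indels as gap columns; when a
  sample's SSC is inverted, its FASTA carries the inversion but the
  alignment keeps the SSC block in reference orientation, as a curated
  comparative alignment would (documented deviation from
  row-equals-genome for that sample).

The default study conditions (`table1_family_config`) are six samples in
the roles of the six berry crops: LSC/IR sizes tuned, via two
size-tuning indels and a mirrored IR-internal indel, to the published
per-accession region-size profile (LSC 104,591–107,607 bp; IR
34,238–43,208 bp; SSC fixed at 3,030 bp, inside the ~3 kb envelope
typical of the group — per-sample SSC variation is not modelled because
the inverted-SSC sample requires a fixed-width SSC block); small IR
boundary shifts (±180 bp max); SSR densities ~0.75/kb in the IRs versus
~0.34/kb in single-copy regions, mononucleotides dominating; ten
polymorphic candidate SSR loci whose allele table resolves only the
bilberry-, cranberry- and southern-highbush-like samples (minimal panel
of three loci, by construction one locus per "separator class"); a
five-allele intergenic indel flanked by rpl36/rps8 that fails only one
sample pair, plus a second indel resolving it (minimal indel panel of
two); 10 private SNPs per sample and 15 shared bi-allelic SNPs; 112
unique genes (74/34/4 by kind) with 19 intron-containing genes, a
trans-spliced rps12 analogue, a psbA-like gene split 236/826 bp across
the LSC/IRA junction, one copy-number-variable tRNA, and one
SSC-inverted sample. The micro profile is the same architecture at
~16 kb for oracle-speed tests. All constants were fixed from the
published per-accession profile before any verification runs and are not
tuned.

## Numerical and determinism notes

Every random draw flows from a single `numpy` Generator seeded from the
user seed; identical seeds give identical bytes. Tie-breaks are stated
and lexicographic throughout (UPGMA pair choice, Kruskal edge order,
consensus symbols, IR candidate selection by score then smallest start).
Degenerate inputs: empty FASTA, duplicate ids, ragged alignment rows,
non-symmetric matrices and zero-length regions raise named errors;
absent IRs and unachievable discrimination targets return structured
results instead of raising.

## What passing tests do and do not show

The synthetic families exercise every variation class the pipeline
claims to handle, with exact expectations — but their background is
deliberately repeat-scrubbed and their alignment is the true one. Real
plastomes carry imperfect repeats, ambiguity codes and aligner-dependent
gap placement; on real data the alignment-mediated counts (orthologous
SSR groups, indel blocks, site classes) inherit whatever the chosen
aligner does in low-complexity regions. Problem sizes used in the test
suite and acceptance script — ~16 kb genomes for oracle-checked
closure, one ~190 kb six-genome family for the headline statistics —
were chosen as the smallest sizes at which every variation class and
both IR copies are simultaneously present at realistic proportions.
Imperfect/approximate SSRs, primer design, bootstrap support and
statistical-parsimony networks are out of scope.
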