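# Methods

## Scope and data model

`plastcomp` analyses annotated plastomes (GenBank flat files) and
pre-computed whole-genome / per-gene alignments (aligned FASTA).  It does not
compute alignments, annotate genomes de novo, or run ML/Bayesian inference;
those are consumed from, or exported to, the external tools a practitioner
would use (MAFFT, PartitionFinder, RAxML/MrBayes).

Internally all coordinates are 0-based half-open; GenBank I/O converts to the
format's 1-based inclusive convention.  Circular genomes are stored
linearized at a canonical origin — the first base of the LSC, immediately
after IRa — giving the fixed region order LSC–IRb–SSC–IRa.  Features that
cross the origin carry a flag and split exons.  Gene symbols are normalized
to the underscore anticodon form (`trnA_UGC`).  Sequences are restricted to
{A,C,G,T,N}; N is treated as missing in every statistic (GC denominators,
SNP calling, distances).

## Inverted-repeat detection

The IR pair is defined as the longest pair of disjoint intervals whose
sequences are reverse complements within a mismatch budget (default 0).
Algorithm: index all k-mers of the reverse-complemented sequence
(k = min(31, min_len/(m+1)), floor 4, so a true repeat always contains an
exact seed), map matches onto anti-diagonals, and on each seeded diagonal
find the longest window containing at most m mismatches by sliding over the
mismatch positions; windows are trimmed so they never start or end on a
mismatch.  Circular genomes are searched on the doubled sequence, candidate
arms reduced mod n, arcs checked for disjointness (which also rejects
palindromic self-matches), and duplicates collapsed.  Ties on length break
by leftmost start, so output is deterministic.  The detector is validated
against an independent dense run-length DP oracle on small genomes and
against planted truth on simulated ones, and is invariant under rotation and
reverse complement of the input.

The two inter-IR segments are labelled LSC (longer) and SSC (shorter); equal
lengths raise an explicit ambiguity error.  If a trnH annotation lies nearer
the far end of the LSC, the genome is reverse-complemented first, matching
the convention that the IRa/LSC junction falls between rpl2 and trnH.
Partitioning returns the rotated record together with the structure, since
rotation changes feature coordinates.

## Region metrics and junctions

Per-region GC is reported half-up to two decimals.  Coding length is the
union of all exon intervals — both IR copies count — and non-coding length
is its complement, so the two always sum to the genome length (the same
convention under which published region tables balance).

Junction reports consider, for each of JLB/JSB/JSA/JLA, the genes within a
5,000 bp window (the border-proximal genes a junction figure would show).
A gene spanning a junction reports the bp of its span on each side (its
"extension" across the boundary); interior genes report their distance to
the junction, 0 if abutting.  JLA sits at the origin, so genes are compared
against their nearest circular image.  Gene pairs sharing bases near a
junction are reported as overlaps (e.g. ndhF against the truncated ycf1
pseudogene at JSB).  A boolean flag records the diagnostic rpl2–trnH
configuration at JLA.

## SNP divergence

A column is a SNP iff its non-missing characters (gaps and N excluded)
include at least two distinct bases; columns with fewer than two
observations are never SNPs.  Indel polymorphisms are deliberately not
counted — this is substitution-only ("only find SNPs") accounting.
Partition labels are projected from a designated reference taxon: each
column takes the region/coding/feature label of the reference base aligned
to it, and reference-gap columns inherit the preceding labelled position, so
character counts are alignment-column counts and partitions remain additive.
Positions inside a gene's span but outside its exons are labelled
`<gene>_intron` (non-coding); positions between genes are labelled by their
flanking gene pair.  Pseudogene exons count as coding — they carry a gene
label, and published totals are consistent with that reading.

Divergence proportion = 100·SNPs/characters, rounded half-up to two
decimals.  The hotspot screen keeps protein-coding features with
250 ≤ length ≤ 1500 bp (inclusive) and divergence strictly greater than
3.5 % — the length bounds and the strict cutoff follow the usual
marker-screening convention — sorted by divergence, then length, then name.

## Supermatrix and trees

Shared genes are protein-coding, non-pseudogenized annotations present in
every input genome; IR duplicates contribute one copy; CDS are spliced and
strand-resolved.  A CDS length not divisible by 3 is retained with a frame
warning and excluded from codon-position schemes.  Genes concatenate in
lexicographic order (any fixed order is valid; this one is reproducible).
Scheme sizes are S1=1, S2=3, S3=k, S4=3k, with codon position defined as
(column − block start) mod 3 + 1.  Writers emit relaxed PHYLIP, NEXUS with
charsets, and RAxML-style partition files (`DNA, gene_pos1 = a-b\3`).

Distances are p or Jukes–Cantor (d = −¾ ln(1 − 4p/3)) over pairwise
comparable (non-gap, non-N) sites.  Neighbor joining is delegated to
dendropy on a distance matrix computed here; taxa are sorted by label before
the computation so the result does not depend on input order.  Because
dendropy's internal join order is not deterministic at floating-point
resolution, trees are serialized through a canonical newick writer (rerooted
at the vertex adjacent to the alphabetically first taxon, children ordered
by smallest descendant label, branch lengths at 8 decimals); this makes
pipeline reruns byte-identical.  NJ here is plumbing for quick topology
checks, not a substitute for model-based inference.

## Synthetic clades

The generator builds a random ancestor (base composition 63 % AT, matching
plastome AT-richness) with an exactly planted IR (IRa = revcomp(IRb)),
annotates it from a template, and evolves it along a newick tree.  Per
branch, each site mutates at most once with probability
branch length × site multiplier, the new base uniform over the three
alternatives (a Jukes–Cantor-like scheme); multipliers compose
region × coding-class × per-gene factors.  Mutations are drawn only in LSC,
SSC and IRb; after every branch IRa is rewritten as revcomp(IRb), emulating
the copy correction that keeps real IRs near-identical and their apparent
divergence low.  No indels are introduced, so leaf sequences form a
positionally exact alignment and the planted SNP columns are unambiguous.

Defaults (scaled-down, ~1/8 of a real plastome; chosen once as the study
conditions for all tests):

| parameter | default | meaning |
|---|---|---|
| lsc / ssc / ir | 11,000 / 4,600 / 2,600 bp | region lengths (total 20.8 kb) |
| tree | 6-taxon, total length 0.0368 subst/site | two nested sisters, two deeper branches, two outgroups |
| r_lsc / r_ssc / r_ir | 1.0 / 2.4 / 0.4 | region rate multipliers |
| r_coding / r_noncoding | 0.5 / 1.05 | coding-class multipliers |
| per-gene factors | 0.3–6.0 | hot marker genes high; ndhF/ycf1 strongly conserved |
| base probs | A,T = 0.315; C,G = 0.185 | AT-rich composition |

The default 19-feature template plants the diagnostic border layout: rps19
spanning JLB (200/79 bp), a truncated ycf1 pseudogene spanning JSB (400/300
bp) overlapping ndhF by 25 bp, ycf1 spanning JSA, rpl2 ending near JLA with
trnH just inside the LSC, and mirrored IR copies of rpl2 and rrn16.  Five
hot marker genes fall inside the usable 250–1500 bp range (rps15, ccsA,
ndhG in the SSC; rpl22 and the junction gene rps19 in the LSC — mirroring
the empirical tendency of hotspots toward the SSC), and two hot genes fall
outside it (accD too long, psbI too short) to exercise the screen's length
filter.  The region multipliers were calibrated, as part of the generator's
design goal, so the realized ordering IR < coding < non-coding < SSC holds
essentially always at default sizes (200/200 probe seeds; the emergent
percentages, e.g. ~0.8 % IR and ~6 % SSC, bracket the gradient reported for
real Cornales plastomes).  Cold protein-coding genes sit ≥3 binomial SDs
below the 3.5 % hotspot cutoff and hot ones ≥3 SDs above, so the screen
recovers exactly the planted set in ≈99.5 % of seeds; with ~10 cold genes
per clade, occasional single-gene false positives are a property of the
statistics, which is why recovery is asserted as a ≥95 % rate rather than
per-seed.

Two single-copy bases flanking each IR end are adjusted whenever a mutation
would make the planted repeat extendable, so detected boundaries equal
planted boundaries exactly; these two guard sites are excluded from rate
tests.  One seeded RNG drives everything in a fixed order (ancestor bases,
then branches in preorder, sites ascending), so identical config + seed
reproduce byte-identical outputs.

What the simulations do **not** emulate: indels and rearrangements, rate
heterogeneity within a rate class, codon structure and selection, base-
compositional drift, and annotation errors.  Passing tests therefore
demonstrate correctness of the accounting and detection machinery under
substitution-only evolution, not robustness to alignment error or structural
variation in real data.

## Numerical choices and degenerate inputs

Percentages round half-up to two decimals (`Decimal`), matching report
precision.  GC of an all-N stretch is 0.0.  Zero characters in a partition
raise an undefined-proportion error rather than returning 0.  JC69 is
undefined at p ≥ 0.75 and raises.  Equal-length inter-IR segments, taxon-set
mismatches between per-gene alignments, ragged alignments, empty inputs, and
a reference row that does not match its annotation all raise typed errors.
Pipeline stages propagate failures with the stage name and leave a MANIFEST
marking the run incomplete; complete runs hash every emitted file.

## Known limitations

* IR detection assumes a single dominant repeat pair; genomes with multiple
  near-maximal inverted repeats would be resolved by the deterministic
  tie-break, not biological insight.
* The mismatch-tolerant mode finds the longest budgeted window per diagonal;
  repeats interrupted by indels (off-diagonal) are out of scope.
* Junction "nearest gene" search uses a fixed window (default 5 kb), which
  on strongly scaled-down simulated genomes includes more than the
  border-proximal genes; on real-size plastomes it matches the conventional
  border-figure content.
* Per-gene supermatrix input must already be aligned (or indel-free, as in
  the simulator); no gap-filling of missing taxa is attempted.
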