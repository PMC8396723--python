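# Methods

## Scope and data model

`plastomma` analyses annotated plastomes represented as a linearized
circular sequence plus a feature list (gene / CDS / tRNA / rRNA, 0-based
half-open coordinates internally; the GenBank boundary converts from
1-based inclusive).  The quadripartite partition is the maximal pair of
disjoint intervals whose sequences are exact reverse complements; the
longer single-copy arc is the LSC and the record is relinearized to start
there, with origin-spanning features split into two segments.  Detection
anchors shared 16-mers between the sequence and its reverse complement,
groups them by diagonal, and extends each anchor to a maximal run; ties
are broken by leftmost start, and overlapping (palindromic) candidates
are rejected.  Exactness is assumed: plastome IRs are effectively
identical copies, and the generator maintains that invariant.  A genome
whose two IRs differ by even one base would be found with a shorter IR.

All variability analyses run on one-IR-removed sequences (IRb dropped,
features clipped) so the duplicated region is not counted twice.

## Region extraction and the 150 bp threshold

CDSs are extracted spliced and strand-corrected; introns are inter-exon
gaps of multi-segment gene features; IGSs are gaps between consecutive
gene-bearing features in linearized plus-strand order, named
`<left>-<right>`.  The conventional 150 bp minimum for noncoding regions
is applied to *aligned* length at the variability stage, not at
extraction — short unaligned extractions can exceed 150 columns after
gapping, and the threshold's natural home is the statistic computed on
the alignment.

## Variability statistics

For an alignment, per column with k distinct states among {A,C,G,T} (gap
and N never count): segregating sites s gain 1 when k ≥ 2, mutations m
gain k − 1, and parsimony-informative characters gain 1 when at least two
states each occur in at least two rows.  m and s are deliberately both
reported: they differ only at multi-allelic columns, and published
variability studies do not always say which entered their SV values, so
this package exposes both and uses m (the mutation count) in SV.

Indel events are distinct maximal gap intervals: per row, maximal `-`
runs; identical (start, end) intervals across rows merge into one event;
nested or overlapping but non-identical intervals stay distinct; terminal
runs touching the first or last column are treated as missing data
(partial sequences otherwise inflate the count).

SV = 100·(m+i)/(l+m+i) with l the alignment length.  Hotspots are the
top-k regions by SV, ties broken by larger m then name.  Pairwise
indel events against a reference taxon are assigned to LSC/SSC/IR by the
reference-coordinate midpoint; a midpoint exactly on a boundary goes to
the region ending there.

## SSR scanning and primers

The scanner reports maximal perfect tandem repeats with repeat-count
minima {1:10, 2:5, 3:3, 4:3, 5:3, 6:3}.  A motif that is itself a power
of a shorter motif is never reported, which implements the
shortest-period rule; loci closer than 100 bp can be grouped as compound
without changing the locus count.  Runs containing N are not reported.
In a partially extended run (length not a multiple of the unit) the locus
is reported at the leftmost phase; scanning the reverse complement
therefore mirrors loci up to that phase, which the tests account for.

Cross-taxon locus identity = overlapping alignment intervals + motifs
equal up to cyclic rotation.  Motifs are reported as observed in
per-genome inventories; rotation-insensitive matching is used only for
cross-taxon identity, and strand-insensitive classes (A/T, AAG/CTT) only
in summaries.

Melting temperature uses the Wallace rule 2(A+T)+4(G+C) up to 20-mers
and Tm = 64.9 + 41·(GC−16.4)/N above (the study's GUI tool does not
state its formula; these are the standard quick estimates and the choice
is configurable).  Candidate generation is sliding windows over 200 bp
flanks — plumbing; the specified computation is the constraint filter,
which records every check per pair.

## Junctions and ndh status

The four junctions are the partition boundaries (JLB, JSB, JSA, JLA).  A
gene is reported at a junction when its span strictly contains the
coordinate; any annotated remnant ≥ 1 bp counts (configurable), since
remnants as short as 15 bp are biologically real.  JSB types: I — ndhF
wholly within the SSC; II — ndhF spanning the junction; III — ndhF
absent; an ndhF wholly inside the IR is flagged unclassified.

A CDS is *intact* when it starts with ATG or a legitimate plastid
alternative (GTG/ACG/CTG/ATT), has length ≡ 0 mod 3, ends with a stop,
contains no internal stop, and is not flagged `/pseudo`.  Status per ndh
gene: complete (some CDS copy intact), pseudogene (annotated but no
intact copy), lost (no annotation).  ndhB is scored from whichever copy
survives IR removal, making the matrix invariant under `drop_one_ir`.

## Codon usage

Counts run over all in-frame CDS annotations (length ≡ 0 mod 3; others
are excluded with a warning; codons containing N are tallied separately).
RF includes stop codons by default — configurable, because published
tables that call a codon "rarest after stop codons" imply stops were in
the denominator.  RSCU is count over the synonymous-family mean under
genetic code table 11; single-codon families are identically 1;
unobserved families are reported as 0 and flagged rather than NaN-ed into
a table.

## Tajima's D

D follows the 1989 formulas (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂).  π is the
average pairwise difference count with pairwise deletion of gap/N sites;
S is counted on complete columns only — the common implementation
compromise when alignments carry ragged missing data; on gapless
alignments the two filters coincide.  With S = 0 the statistic is
undefined and the result is classed "not computed".  The p-value uses the
beta approximation of the null density on [D_min, D_max], with the normal
approximation reported alongside.  The labels follow the source
convention (significant D < 0 → "positive", D > 0 → "purifying"); D also
responds to demography (expansion mimics negative values, structure
positive ones), so the classes are a screen, not a demonstration of
selection — the caveat is reproduced, not reinterpreted.

## Genome metrics and correlations

The per-taxon table (total/LSC/SSC/IR lengths, %GC, ndh counts,
per-region indel events) validates additivity total = LSC + SSC + 2·IR
per row.  Violations are flagged and never silently corrected; an
explicit fix mode recomputes LSC as total − SSC − 2·IR.  The bundled
published ten-taxon table carries exactly one such violation
(*Anathallis obovata*: the printed LSC is 3,000 bp too large, and the
stated LSC range implies the corrected value 83,694).  Pearson r uses the
two-sided t transform with n − 2 degrees of freedom.  The published LSC
range (1,906 bp) is inconsistent with any single resolution of that row
(the corrected table gives 1,911), so only the SSC and IR ranges are
treated as checkable.

## The synthetic family generator

The generator builds a quadripartite ancestor from a gene roster —
default: ~80 genes, LSC 84 kb / IR 26 kb / SSC 17.8 kb, GC 0.37, ndhB in
the IR, ndhC/J/K in the LSC, the other seven ndh genes in the SSC, ycf1
spanning the SSC/IRa junction (1 kb into the IR), rpl22 spanning LSC/IRb
(33 bp) — then derives taxa by planting events relative to the ancestor:

* substitutions at distinct positions (infinite sites), each with a
  random taxon subset and derived base;
* deletions with known boundaries and sharing patterns (geometric
  lengths, mean 4 bp), at least 2 bp apart so maximal gap runs map
  one-to-one to events;
* SSR loci in spacers, with per-taxon repeat counts realized as
  tail-unit deletions and flanking bases forced to break the period so
  the planted run is exactly maximal;
* ndh fates per taxon: complete (protected from edits), pseudogene (a
  1 bp frameshift deletion), lost (whole-span deletion — which also
  shrinks the SSC, reproducing the size correlation).

Default event densities are calibrated to the study system: 0.08
substitution events/bp and 0.018 deletion events/bp in single-copy DNA
(matching ~8 % variable characters and ~2,400 indel events over a
~130 kb one-IR genome family-wide), with the IR at 0.15 of those rates.
Background deletions are placed only outside exons, because selection
removes frame-disrupting indels from real coding regions; substitutions
may hit any unprotected position.  IR edits are applied to IRb and
mirrored into IRa, so the mirror invariant is exact by construction; the
single-copy bases flanking the IRs are pinned non-complementary so the
detected IR is exactly the constructed one.

Because every edit is a substitution or deletion, the true multiple
alignment of any ancestor window is available in closed form, and m, i,
SV, SSR repeat counts, ndh statuses and junction types all have exact
expectations.  What the generator does *not* emulate: insertions relative
to the ancestor, inversions and rearrangements, substitution-model
structure (transition bias, rate heterogeneity), recurrent mutation,
alignment error, and annotation error.  Passing tests therefore
demonstrate that the statistics are computed correctly, not that an
external aligner would reconstruct the true homology on hard real data —
which is why the real-data reproduction quantities are exposed as checks
(`plastomma.reproduction`) rather than asserted.

Junction-type II (ndhF across JSB) is exercised through single-genome
construction: its IR overlap zone and a ycf1 overlap cannot both be
specified freely (the IRb end cannot mirror two different gene tails), so
a type II genome sets the ycf1 overlap to zero, and the validator rejects
contradictory configurations.

The neutral-alignment simulator wraps a haploid Kingman coalescent
(msprime, population size 1) with infinite-sites binary mutations at rate
θ/2, so E[S] = θ·a₁ and E[π] = θ; variant sites are placed at distinct
random columns over an A background.  It exists to calibrate the Tajima
machinery, and its expectations are verified against the closed forms in
the tests (2,000 replicates, three standard errors).

## Problem sizes used in verification

The test suite and the acceptance script run the generator at its default
study scale (ten ~150 kb genomes) for truth-recovery checks; structural
and pipeline tests use a reduced roster (~16 kb genomes, five taxa);
scanner/detector oracle comparisons use 5 kb sequences and ≤ 10×50
alignments where exhaustive enumeration is the oracle; the Tajima null
calibration uses 500 replicates at n = 10, θ = 5.

## Known limitations

* IR detection requires exact repeats and a genome not linearized inside
  an IR; degenerate IRs or origin-spanning IRs are not handled.
* Imperfect/compound-interrupted SSRs are out of scope (perfect repeats
  only, MISA semantics).
* The aligner is external by design; results on real data inherit its
  version-to-version variation.
* Tree inference, bootstrap support and substitution-model fitting are
  out of scope.
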