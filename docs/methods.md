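# Methods

This note documents the models, rules and numerical choices behind the
package, and what its synthetic-data tests do and do not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based, half-open. GTF files and QTL/position
tables are 1-based inclusive on disk, BED is 0-based half-open; conversion
happens only at the I/O boundary, so a GTF exon printed `101–200` is the
internal interval `[100, 200)` and round-trips exactly. The gap between two
half-open intervals is `max(starts) − min(ends)` (0 when touching); an
intersecting pair has no distance (`None`), and intervals on different
chromosomes are infinitely far apart.

## Positional classes and loci

A query transcript is **intergenic (u)** iff none of its exons overlaps any
annotated gene span (protein-coding or known lncRNA), where a gene span is
the hull of all its transcripts; **intronic (i)** iff its whole span lies
inside a single intron of some protein-coding isoform (all isoforms'
introns are eligible); **overlap** otherwise. Strand is ignored for both
calls — the intronic class is containment-based and the source material
does not prescribe strandedness, so a stranded variant was deliberately not
invented. Transcripts cluster into gene loci by transitive same-strand
exonic overlap (≥ 1 bp); locus ids take the lexicographically smallest
member id so the clustering is order-independent and deterministic.

## The filtering funnel

Filters run in a fixed order (class selection, structural, expression,
homology, domain, coding vote, ORF, proximity); because each rule is
per-transcript and independent of the others, the surviving set is
order-invariant — only the per-step report changes. Thresholds follow the
strict/inclusive readings of the published wording:

| rule | keep condition | default |
|---|---|---|
| length | spliced length **>** 200 nt | 200 |
| mono-exon length | not (1 exon and length **>** 10 kb) | 10 000 |
| mono-exon repeat | not (1 exon overlapping a repeat ≥ 1 bp) | — |
| expression | FPKM **≥** 1 in **≥** 2 samples, breeds pooled | 1.0 / 2 |
| homology | no UniProtKB/miRBase/Rfam hit with E **<** 10⁻⁵ | 1e−5 |
| domain | no reported Pfam hit (no E cut-off; optional flag exists) | — |
| coding vote | < 3 of {CPC2 > 0.5, CNCI > 0, CPAT > 0.36, PLEK > 0, FEElnc coding} | 3 |
| ORF | longest ORF **<** 300 aa | 300 |
| proximity (u only) | distance to any coding gene **≥** 1 kb | 1000 |

A missing FEElnc label counts as a noncoding vote (no score cut-off exists
for it). The ORF finder scans the three sense frames only (the transcript
is already stranded), starts at ATG, counts codons up to but excluding the
stop, and also counts 3′-partial ORFs that run off the sequence end;
codons containing N are treated as ordinary non-start, non-stop codons.
Missing expression rows reject the transcript with a distinct reason;
missing evidence rows for transcripts that reach the evidence stages are a
hard error listing the offenders, because silence there would be
indistinguishable from a clean pass.

## Expression calls

A lncRNA is breed-specific iff it has FPKM ≥ 1 in at least two samples of
one breed and FPKM < 1 in every sample of the other; both cut-offs reuse
the funnel's definition of "expressed" and are configurable. Differential
expression itself is consumed from an upstream Cuffdiff-style table — the
beta-negative-binomial fit is not re-implemented — and thresholded at
FDR ≤ 0.1, with direction up iff the first breed's mean exceeds the
second's. On the published DE table all eight printed rows pass FDR ≤ 0.1
(six up, two down by the printed means) although the accompanying text
counts seven DE lncRNAs with a different up/down split; the package
implements the stated rules on the printed numbers and does not attempt to
reconcile the narrative. Gene-level expression, where needed, is the sum
of member-transcript FPKM. qPCR validation uses the comparative-Ct method:
ΔCt per sample against the housekeeping gene, ΔΔCt against the baseline
condition's mean, fold change 2^−ΔΔCt.

## Target prediction

Cis targets are the nearest protein-coding genes strictly left and right of
a lincRNA hull, reported when the gap is ≤ 100 kb (ties on one side are all
reported); an ilncRNA's target is its host gene, and its "flanks" are the
host on both sides. Trans targets take all (lncRNA, coding-gene) pairs with
|r| above the cut-off and a two-sided p below 5·10⁻⁵, where p comes from
the exact t transform t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom —
standard for a Pearson coefficient, since no test was named in the source.
Two cut-offs coexist deliberately: 0.99 for target calling and 0.95 for the
co-expression edges feeding the network, matching the two uses described.
Zero-variance profiles are skipped and logged. Note that with n = 6 samples
the p cut-off is the binding constraint (|r| ≈ 0.993 at p = 5·10⁻⁵).

## Conservation and synteny

A transcript is conserved in a species iff any BLAST hit in either query
direction has E ≤ 10⁻⁵; the per-species mean alignment length is taken over
the best hit (lowest E, longest alignment on ties) per conserved
transcript. Synteny is sequence-free: the sheep lincRNA's flanking pair
(X, Y) is conserved in a species iff some foreign lincRNA's nearest
flanking coding genes are exactly {ortholog(X), ortholog(Y)}. Matching is
unordered and orientation-blind by default (a strict-order mode exists);
requiring equality of nearest-flank pairs is the stricter reading of
"locates between X and Y". Orthology is an input table; missing orthologs
or an incomplete flank make the record non-conserved with an explanatory
flag, never an error.

## QTL co-localization

A lncRNA gene is annotated to a QTL iff its start and end both lie inside
the QTL interval on the same chromosome — strict containment, not overlap,
at the gene-locus level. Optional filters restrict to a trait substring
(e.g. "Tail fat deposition") and to QTL spans strictly under a bound
(1 Mb in the published analysis). AnimalQTLdb-style GFF dumps and plain
5-column TSVs are both accepted; `Chr.` prefixes are stripped.

## Network modules

Co-expression edges carry weight |r|; PPI edges carry score/1000 when a
STRING-style 0–1000 scale is detected; duplicated pairs keep the maximum
weight with sources concatenated. Modules maximize the cohesiveness
objective f(V) = w_in / (w_in + w_bound + α·|V|) by greedy single-step
add/remove moves from every uncovered seed (α = 2 by default, ties broken
toward additions and then by node id, so detection is deterministic).
Candidates overlapping by ω(A,B) = |A∩B|²/(|A|·|B|) ≥ 0.8 merge; modules
must have > 5 members; significance is a one-sided Mann–Whitney U over
member nodes comparing in-module vs out-of-module incident weight, kept at
P ≤ 0.01. Because the growth step already maximizes internal weight, that
rank test alone is anti-conservative on random graphs; candidates must
therefore also clear the standard minimum internal-density floor (0.5 for
unit-weight graphs, 0.3 for weighted ones, configurable). With the floor,
Erdős–Rényi nulls (n = 60, p = 0.05) yield no significant module in 20/20
seeded runs while planted cliques of sizes 9–12 among ~300 noisy nodes are
recovered exactly.

## Enrichment

Over-representation of a query gene set against a GMT collection uses the
hypergeometric upper tail P(X ≥ k) with the full background as population,
Benjamini–Hochberg adjustment across all tested sets, and FDR < 0.05 as the
significance call. The pipeline runs one test battery per detected module
(falling back to the trans-target gene set when no module passes). The
background defaults to the annotation's protein-coding genes plus all
coding-kind network nodes; any background can be passed explicitly.

## The synthetic world

`generate_world` lays out coding genes (2–12 exons) along a few synthetic
chromosomes with ~60–80 kb intergenic gaps and plants, with full ground
truth: candidate lincRNAs ≥ 10 kb from genes and ilncRNAs inside widened
introns; one decoy cohort per funnel rule, each violating exactly that
rule; breed-specific expression rows (10 + 5 lincRNA and 2 + 1 ilncRNA
genes, the study's reported split, over 3 + 3 samples); trans pairs drawn
from a shared latent profile (|r| > 0.999 verified before writing, two
negative) plus uncorrelated decoy pairs (|r| < 0.5); conservation hits
whose per-species alignment lengths average exactly 284 nt (bovine) and
312 nt (human), the reported means; nine loci syntenic in all three
foreign species plus partially syntenic ones; seven DE lncRNAs; QTL
intervals anchored on planted loci with spans straddling 1 Mb (containment
truth recorded by direct arithmetic over the layout, since wide QTL
legitimately contain bystander loci); three PPI cliques of sizes 9–12 with
~0.9 weights among ~300 nodes over sparse 0.15–0.4 noise; and one planted
enriched gene set. Expression noise is log-normal with σ = 0.2 on the log
scale, small enough that planted truth stays crisp at n = 3 per breed.
A fixed seed fixes every output byte.

What the generator does **not** emulate: read-level sampling noise,
assembly artifacts (fragmented or chimeric models), realistic FPKM
dispersion and length biases, sequence-level homology (evidence tables are
written directly rather than derived from the sequences), overlapping gene
structures, or database-version effects on enrichment content. Passing the
planted-recovery suites therefore demonstrates that the rules and
algorithms are implemented correctly and are well-calibrated on clean
signals — not that the pipeline's biological yield on real data matches any
particular study's counts, which depend on the raw sequencing data and
external databases and are out of desk-scale reach.

## Problem sizes and determinism

Default world scale: 3 chromosomes, 60 coding genes, 9 known lincRNAs, 30
planted lincRNAs, 6 ilncRNAs, 45 decoys, 6 samples, ~290 network proteins
— sizes chosen so every planted structure is represented several times
over while the full test suite and the acceptance script each complete in
seconds. All randomness flows from a single integer seed through one
`numpy` generator; pipeline outputs are byte-stable across reruns, with
all orderings fixed by explicit sorts.

## Known limitations

* The intronic class ignores strand; antisense intronic transcripts are
  not distinguished.
* The module p-value is a pragmatic post-selection test, interpretable
  only together with the density floor; it is not a calibrated FDR across
  modules.
* Trans-target p-values assume bivariate normality; with n = 6 samples
  they are best read as a ranking device, as in the source analysis.
* The DE model itself is consumed, not checked; garbage FDRs in produce
  garbage calls out.
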