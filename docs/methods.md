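# Methods

`clipmod` implements the downstream computational analysis of an
iCLIP/miCLIP study of an RNA-binding protein that steers an m6A/m6Am
demethylase to its targets: single-nucleotide crosslink-site calling from
truncation data, classification of miCLIP truncation peaks into m6A and
m6Am sites, length-standardized metagene profiling, anchored density
profiles with matched random-site nulls, peak-overlap statistics, and
site-level count comparisons.  Every stage is testable end-to-end on
synthetic data with planted truth; this note records the models, the
defaults and the design choices.

## Coordinates and annotation

All internal coordinates are 0-based, half-open, stranded.  BED I/O is
native; GTF (1-based, inclusive) is converted at the boundary.  A
transcript model carries its exons, the genomic CDS span, and derived
5'UTR / CDS / 3'UTR / intron features; on the minus strand the 5'UTR is
the genomically 3'-most block and all offsets are measured 5'→3' in
transcript sense.  The stop codon is treated as part of the CDS exactly
as annotated — no adjustment.  When isoforms overlap, operations that
need one transcript per position use the *representative* transcript,
defined as the one with the longest mRNA (ties broken lexicographically
by id).  This is a package convention, not something the underlying
analysis specifies; it is configurable wherever it matters.

## CITS calling

iCLIP cDNAs truncate at the crosslinked nucleotide, so each read
contributes one truncation event at the position immediately 5' of its
start in read orientation (plus-strand read `[s, e)` → `s − 1`;
minus-strand read → `e`).

Candidate sites are scored against a uniform within-transcript null.
For a transcript whose genomic (pre-mRNA) span has length `L` and
carries `n` truncations, a position with `k ≥ min_count` events gets

    p = P(X ≥ k),  X ~ Binomial(n, 1/L).

The pre-mRNA span (introns included) is the background unit because CLIP
signal in this setting is heavily intronic; using exonic length only
would misstate the null.  Each genomic position is tested once, under
its representative transcript.

**Multiple testing.**  Benjamini–Hochberg correction is applied jointly
genome-wide, and the correction family is every nucleotide of every
covered transcript — not merely the positions that reached `min_count`.
Positions below the threshold carry an implicit p = 1: they can never be
called, but they count toward the family size.  This matters: if the
family is shrunk to the data-selected positions, the realized false
discovery rate under a uniform background inflates several-fold past the
nominal level (we measured ≈0.06 at a nominal 0.01); with the full
family the empirical FDR is ≈0.01.  `min_count` defaults to 2 —
singleton truncations are untestable signal.  Sites with q ≤ 0.01 are
significant (the workflow's stated decision rule).

Per-replicate site lists are filtered against a GFP-only control by
exact (chromosome, strand, position) identity — windowed matching is
available as an option — and then merged across replicates: sites with
at most `gap` intervening bases collapse to the position with the
highest summed count, ties resolving to the 5'-most position in
transcript sense.  iCLIP densities can be normalized to a size-matched
input (SMI) library as per-bin `(CLIP CPM + ε) / (SMI CPM + ε)` with
ε = 0.5 CPM.

## m6A / m6Am classification

From two miCLIP replicates' CITS:

1. **Merge** across replicates at a maximum gap of 1 bp.  "Gap of 1" is
   read literally as at most one intervening base: positions 100 and 102
   merge, 100 and 103 do not.
2. **Extend** each merged peak 2 nt both upstream and downstream
   (strand-independent, clipped at chromosome boundaries).
3. **m6A**: scan the sense-strand sequence of each extended peak for
   DRACH 5-mers (D∈{A,G,U}, R∈{A,G}, A, C, H∈{A,C,U}; DNA T↔U).  The
   motif's central A must lie inside the extended peak; the outer bases
   may extend up to 2 nt beyond it.  Every qualifying A becomes one m6A
   site (a peak may yield several); 5-mers containing N never match.
4. **m6Am**: within each extended peak, maximal runs of sense-strand A
   are collapsed and the 5'-most A of each run (in transcript sense)
   becomes a candidate — m6Am sits at the first transcribed nucleotide,
   so the 5'-most representative is the biologically coherent choice.
   Candidates are kept when they fall within the first
   `floor(0.25 × utr5_length)` nt of the 5'UTR of *any* annotated
   transcript (the permissive reading; a representative-only mode is
   available), and dropped when they coincide with an m6A coordinate.

The two output sets are disjoint by construction, every m6A coordinate
is verifiable against the genome (base A, DRACH context), and the
classifier is deterministic: identical inputs give byte-identical BED
output.

## Metagene profiles and feature distributions

Each transcript's 5'UTR, CDS and 3'UTR are rescaled to 50 / 100 / 70
bins (configurable; chosen to echo typical UTR:CDS length ratios).  An
event at transcript-sense offset `o` in a region of length `R` falls in
bin `floor(o/R × bins)`.  Per-transcript binned profiles are scaled to
events per million library events and averaged unweighted over
transcripts; transcripts lacking any of the three regions are excluded
from averaging rather than silently misassigned, and intronic events are
not part of the three-region profile.  The profile is invariant to
transcript length and to global count scaling.

Feature distributions report peaks per region either raw (percent of
peaks over 5'UTR/CDS/3'UTR/intron/noncoding/intergenic) or per Kb of
summed region length over the assayed transcripts (one representative
per gene); `count = peaks_per_kb × length_kb` holds exactly and
intergenic peaks are excluded from per-Kb denominators.

## Anchored density profiles and nulls

Around a set of single-nucleotide anchors, the truncation density (CPM)
is averaged over strand-aware offsets −W..+W (default W = 500 for
plotting; tests use W = 100), with positive offsets 5'→3' in transcript
sense so "downstream" is biologically meaningful.  SEM is computed
across anchors.  Windows running off a chromosome are truncated and
counted.

A matched random-site null of exactly the same size is drawn from
transcribed positions, stratified by region type (5'UTR/CDS/3'UTR/
intron) and chromosome to match the anchors' composition — the source
analysis never defines its "random sites", so the construction is
explicit here and a uniform-transcriptome alternative is provided;
empty strata fall back to the unstratified pool with a warning.  The
test statistic is the per-site summed density within ±Q nt (default
Q = 100), compared between real and random anchors with a two-sided
Wilcoxon (Mann–Whitney) rank-sum test (ties mid-ranked, asymptotic with
continuity correction).  Under a track independent of the anchors the
p-values are approximately uniform (verified by simulation).

Peak overlap follows the 50-nt rule: both peak sets are extended 50 nt
per side and a peak of A counts as overlapping when it shares at least
1 nt with any extended B peak (strand-aware by default).

## Counts and group comparisons

Site-level counts sum truncations within site ± 2 nt (mirroring the
classification window).  Size factors are DESeq-style median-of-ratios
over rows positive in all samples, falling back to library-size ratios
when fewer than 10 such rows exist.  Two groups are compared with a
two-sided Mann–Whitney U on pooled normalized per-row values; three or
more with one-way ANOVA plus Tukey-HSD pairwise contrasts.  Tests run
on normalized values, not logs — rank tests are invariant to monotone
transforms; `log2(x+1)` is used for display only.  A negative-binomial
differential model is deliberately out of scope.  qPCR relative
quantification is the closed form `RQ = 2^−((CTt−CTr)−(CTt0−CTr0))`.

## Synthetic data

The generator emulates the study's data regimes on a small random
genome (default: 40 multi-exon coding transcripts on 2 chromosomes,
5'UTR 120–300 nt, CDS 400–900 nt with 1–3 introns of 200–600 nt, 3'UTR
150–400 nt).  Defaults are the study conditions used throughout the
tests: 20× enrichment at planted sites over a Poisson background of 0.5
truncation events per transcribed nucleotide, 2 replicates per
condition, knockdown attenuation 0.3, a GFP artifact-site set 5% the
size of the true set, 60 planted crosslink sites, 50 m6A and 30 m6Am
sites.

Planted m6A sites have a DRACH 5-mer written into the genome in CDS or
3'UTR (where such sites concentrate in real data), with flanks chosen
so that exactly one DRACH center exists within the ±2 classification
window — this keeps the planted truth unambiguous.  Planted m6Am sites
are lone adenosines (sense context `CCCCACCCC`) within the first
quarter of a 5'UTR, so the planted A is the 5'-most of its run and no
accidental DRACH arises.  Crosslink sites are exonic positions without
any sequence context.  All planted positions keep ≥12 nt mutual
distance.

Truncation counts are drawn Poisson per transcribed (pre-mRNA)
nucleotide, multiplied by the enrichment at planted sites; each event at
position p is emitted as a read starting one nt 3' of p, so truncation
extraction inverts the simulation exactly.  SMI libraries have no
enrichment anywhere; the GFP control enriches only its own artifact
sites.  Everything is deterministic under the spec seed (sub-seeds are
derived per assay/condition/replicate and stay below 2³¹).

**What the generator does not model** — and hence what passing tests do
not show about real data: sequencing error, PCR duplication, fragment
length variation, mappability, non-uniform background (GC or expression
driven), overlapping gene models, alternative isoform usage, intergenic
noise (available but off by default), and crosslinking sequence bias.
Recovery rates near 100% on synthetic data reflect a clean Poisson
world; on real libraries the caller's FDR control is the property that
transfers, not the sensitivity numbers.

## Numerical choices and degenerate inputs

Binomial tails come from `scipy.stats.binom.sf`; BH with an externally
fixed family size is computed directly (sort, scale by `m/rank`,
monotonize).  Empty tracks, empty anchor lists, an empty SMI library,
sub-two-replicate miCLIP input, groups of size zero, gene sets that
cover nothing or everything — all raise immediately with messages naming
the violated requirement.  Malformed GTF lines raise a parse error
naming the line number; transcripts whose CDS is not contained in their
exons are skipped with a logged warning.  Site positions mapping to no
transcript are reported (not silently dropped) by the callers and
bucketed as intergenic by the distribution code.

## Problem sizes used in the test-suite and acceptance script

Null FDR calibration runs 50 uniform-background libraries on a
20-transcript genome; site recovery runs the full default conditions
(40 transcripts, 50 m6A + 30 m6Am sites, 2 replicates); the knockdown
contrast plants 300 m6A sites on a 60-transcript genome; the Wilcoxon
null calibration draws 200 independent track/anchor repetitions with 300
anchors each; oracle-equivalence checks run 1000 randomized trials per
primitive.  These sizes were chosen so that each check has clear
statistical resolution while the whole suite stays interactive.
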