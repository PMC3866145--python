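# Methods

This note documents the models, algorithms and numerical choices behind
`mitodui`, and what the synthetic data generator does and does not emulate.

## Genome model

A mitogenome is the deposited light (L) strand of a circular molecule plus
ordered feature annotations.  Coordinates are 0-based, half-open, on the L
strand; a feature spanning the sequence origin carries a `wraps_origin` flag
rather than a split interval.  GenBank's 1-based closed (possibly joined)
locations are converted at the I/O boundary.  Gene labels are canonicalised
(cox1/2/3, nad1–6 + nad4L, atp6/8, cob, rrnS/rrnL, trnX with S1/S2 and
L1/L2 disambiguation, FORF/MORF) so that records annotated with different
naming conventions are comparable; duplicate canonical labels are an
annotation error.

Two half-open intervals that abut do **not** overlap; an overlap requires at
least one shared base.  Intergenic ("unassigned") regions are the maximal
feature-free arcs of the circle; an arc through the origin is reported once.
These definitions satisfy an exact conservation law used as a test
invariant: feature spans − overlaps + intergenic lengths = genome length.
tRNA and rRNA boundaries are taken from annotations as deposited; no
de-novo structural annotation is attempted.

The ORF scan reports, for each strand/frame/stop-segment, the ORF defined by
the 5′-most start codon (default start set: ATG, ATA, ATT, ATC, TTG, GTG —
the conventional plus alternative invertebrate mitochondrial starts); the
span includes the terminating stop codon, the amino-acid length does not.
The invertebrate mitochondrial code (translation table 5) is the default
throughout.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed over unambiguous
bases only (ambiguity codes are excluded from numerators and denominators
and tallied separately).  Whole-genome statistics are computed on the L
strand as deposited; gene partitions on strand-corrected sense sequences.
This reproduces the sign structure typical of these genomes: positive AT
skew on the L strand, negative AT skew and positive GC skew on the protein
sense strand.  Codon-position partitions are taken in reading frame from
the concatenated sense CDS; the gender-specific ORF is excluded from the
protein partition by default (and atp8 included), with switches for both,
since conventions differ between studies.  RSCU for a codon is its count
divided by its synonymous family's mean count; families with no
observations yield NaN rather than an arbitrary zero.

## Divergence

Per gene: terminal stop codons are stripped, peptides are aligned globally
(Needleman–Wunsch through Biopython's PairwiseAligner; BLOSUM62, gap open
10, extend 1, first optimal traceback for determinism), and the peptide
alignment is imposed back on the codons ("retro-alignment") so nucleotide
columns stay in frame.  A pairwise aligner is used deliberately: the F-vs-M
comparison is pairwise per gene, so a progressive multiple aligner would add
an external dependency without changing the two-sequence optimum.  Small
differences in the last printed digit relative to other alignment programs
are expected and documented here rather than hidden.

p-distances use pairwise deletion of columns containing gaps or ambiguity
codes.  Standard errors come from a site-resampling bootstrap (default
1000 replicates, seed 42); on iid sites this reproduces the binomial
closed form √(p(1−p)/n), which is a test oracle.

Ka/Ks follows the classic unweighted Nei–Gojobori (1986) counting method:

* synonymous sites per codon = Σ over positions of (synonymous one-step
  changes)/3, averaged over the two sequences; changes that would create a
  stop codon count as nonsynonymous, which keeps S + N = 3 × codons exact;
* observed synonymous/nonsynonymous differences per codon pair are averaged
  with equal weight over all minimal-substitution pathways that avoid stop
  codons (if every pathway passes through a stop, all pathways are used —
  a rare, documented fallback);
* proportions ps = Sd/S and pn = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − (4/3)p); proportions ≥ 3/4 raise a saturation error;
  Ks = 0 yields an undefined ω, never 0.

Codon columns with a gap or ambiguity in either row are masked whole.
Concatenation joins per-gene codon alignments in a declared order, emits a
partition map, and can drop codon positions (dropping position 3 leaves
exactly 2/3 of the columns).  The "all proteins" summary is computed on the
concatenation of the 13 protein-coding genes with the gender-specific ORFs
excluded.  rRNA genes are compared at the nucleotide level with a plain
nucleotide global alignment (match 2, mismatch −1, gap 5/1).

## TESTCODE

Fickett's statistic combines, for each base, a position parameter
(max over the three frames of the base's per-frame count divided by
min + 1) and a content parameter (the base's frequency), each mapped
through the published interval lookup tables and combined with the
published weights.  The classification thresholds are the published ones:
score ≤ 0.74 noncoding, ≥ 0.95 coding, in between no opinion.  The
score→percent-probability-of-coding table is a monotone reconstruction of
the original calibration anchored at two published points (a score just
below 1.0 ↦ 92%, scores ≥ 1.20 ↦ 100%); the verdicts do not depend on it.
Sequences shorter than the recommended 200 nt window are scored but
flagged low-confidence.  Whether the stop codon is included is the
caller's choice; the pipeline scores annotated ORFs without it.

## Tandem repeats and control regions

The repeat detector compares the sequence with itself at every candidate
period p (default 20 ≤ p ≤ n/2): exact seed runs (12 bp, or p if shorter)
are extended by whole periods while the marginal window's identity stays
above the threshold (default 0.85), then base-by-base under a trailing-
window criterion so that flanking noise is not absorbed.  Overlapping
detections are resolved by a period-minimality rule — a candidate is
dropped when a smaller-period detection covers most of its span at
practically the same identity (within 0.03) — then by identity, period,
span and position.  This guarantees a perfect (unit)^k string is reported
once at the minimal period, and that a period multiple never outranks the
true period because of copy-to-copy mutation noise.  Copies may be
fractional; reports round to three decimals.

Stem-loop potential is combinatorial base-pair maximisation (Nussinov
recursion, minimum loop 3, GU pairs allowed) — a deliberate substitution
for thermodynamic minimum-free-energy folding, which would require an
energy parameter set out of scope here.  The criterion therefore tests
"stem-loop potential", not ΔG.  The traceback is deterministic (outermost
compatible pair first, leftmost bifurcation) and the reported stem is the
longest contiguous helix of the optimal structure.  For sequences up to
18 nt the DP optimum is verified against exhaustive enumeration in tests.

Control-region candidates are the unassigned regions scored by
z(length) + z(AT%) + 1.0·[has a repeat whose unit folds into a hairpin
with ≥ 5 contiguous pairs and loop ≥ 3], z-scores taken across the
genome's unassigned regions.  The criteria come from the comparative
literature; the equal weighting is the minimal assumption and every
threshold is a keyword argument.  Ties break by length, then by the
upstream flank label (unique per junction and rotation-invariant, unlike
raw coordinates).

## Gene order

A gene order is a signed circular permutation (sign = strand).  Reading the
circle from the opposite strand is the same physical genome, so
canonicalisation reorients (reverse + sign flip) when the anchor gene
(*cox1*; lexicographic fallback) carries −, then rotates it to the front.
Adjacencies are identified under (a, b) ~ (−b, −a) for the same reason;
a literal reflection that keeps strand annotations is a distinct order.
Breakpoint distance = adjacencies of one order absent from the other;
with equal gene sets it is symmetric, zero iff the canonical orders are
identical, 2 for an internal segment inversion and 3 for a single-gene
transposition.  Synapomorphic adjacencies are those present in every member
of a designated group and absent from every non-member.

## Neighbor joining

Saitou–Nei NJ with deterministic tie-breaking (the minimal-Q pair with the
lowest index order), negative branch lengths clamped to zero with a log
entry.  It exists to exercise topology-level properties — exact recovery of
additive matrices, and the reciprocal monophyly of F and M taxa on
DUI-style distance matrices — not to replace likelihood or Bayesian
inference, and no support values are computed.

## Synthetic data generator

`simulate_genome` realises a declarative spec: a gene roster in circle
order with per-junction gaps (negative = overlap), per-partition
composition targets, and an optional control-region spec (length, AT%,
repeat period/copies/identity, hairpin-capable unit).  Backbone and
RNA-gene sequences are sampled from base probabilities solved in closed
form from (AT%, AT skew, GC skew); protein genes are built as start codon +
stop-free codons sampled from per-position probabilities + stop codon.
Because overlapping genes overwrite each other's bases, terminal codons are
re-written in a final pass (conflicting constraints are a validation
error), and a bounded deterministic repair pass removes any in-frame
internal stop an overlap created, never touching protected terminal-codon
bases.  The control-region repeat unit is drawn repeatedly and the draw
closest to the regional AT target kept (the unit is amplified `copies`
times, so its composition error would otherwise be amplified with it); the
planted hairpin is a 12 bp inverted repeat separated by a 5 nt loop.
Everything is reproducible from the spec seed.

`evolve_codon_sequences` is a proposal/acceptance process: uniform
single-base proposals, stop-creating proposals rejected, synonymous
proposals accepted, nonsynonymous accepted with probability ω; proposal
rounds continue until the NG86 synonymous difference proportion reaches the
value implied by the Jukes–Cantor-inverted Ks target.  This is deliberately
not a full GY94 rate matrix — there is no transition/transversion
parameter, no among-site rate variation and no indel process — and the ω
recovery tolerance in the tests (20% at 3000 codons) reflects that.  For
the fixture pair the proposal kernel is instead drawn from the target codon-
position base frequencies, making the process stationary at the planted
composition; NG86's equal-rate assumption then biases ω̂ upward by roughly
10–15% at these divergences, which is why single-gene estimates are asserted
as a purifying-selection band rather than a tight recovery.

### The literature-conditioned fixture pair

`solenaia_like_pair` builds a female-type and male-type genome whose
architecture follows the published description of the *Solenaia carinatus*
mitogenomes: sizes 16716/17102 bp; the printed per-gene lengths and
start/stop codons; 27/23 unassigned regions; 2 overlaps (1–8 bp) in F and
6 (1–168 bp) in M including nad6/nad4 = 168 bp and the cox3/cox1 = 8 bp
junction across the origin; rrnS–trnK–trnT–trnY–rrnL; FORF in the
trnE–trnW region and MORF between nad4L and trnD; control regions of
1049 bp (nad5–trnQ, 8 × 101 bp repeat) and 848 bp (trnH–trnQ, 7 × 102 bp);
and the female-lineage gene order that differs from the common unionoid
PCG+rRNA order by the relative position of nad2 and nad3.  Where the full
38-gene map is not published (the placement of the remaining tRNAs, the
exact sizes of the unnamed gaps, the strand set beyond the stated
constraints), the fixture makes one deterministic choice and keeps it.
Male protein genes are evolved from the female ones (ω = 0.33, synonymous
divergence 1.3 — the scale of the concatenated-protein estimates for this
species pair), trimmed or extended to the male lengths; rRNAs are mutated
copies at the published nucleotide p-distances (0.291/0.289).

What the generator does **not** emulate: real tRNA secondary structure,
indels, among-site rate variation, genuine replication-driven skew
gradients around the origin, or the sequence content of the real deposited
genomes — so tests against the fixture validate the *machinery* (counting,
alignment, detection, ranking) under the published architecture, not the
real sequences themselves.  Realised compositions track their targets to
about ±2 AT percentage points; whole-genome skews are emergent from the
mixture of partitions rather than planted directly.

## Problem sizes

Defaults keep every stage fast: the fixture pair generates in about a
second; the full divergence table with 1000 bootstrap replicates runs in a
few seconds; ω-recovery simulations use 3000 codons and 5–8 replicates;
hairpin DP is applied to repeat units (~100 nt), with the exhaustive oracle
limited to 18 nt; NJ property tests use 5–8 taxa.  These sizes were chosen
so the whole suite documents the methods' behaviour in well under a minute
of compute while keeping every statistical assertion comfortably powered.

## Known limitations

* The aligner is pairwise; multi-taxon codon alignments and alignment
  trimming/ambiguity masking are out of scope.
* NG86 is the classic equal-pathway-weight estimator; no maximum-likelihood
  dN/dS, no transition/transversion weighting.
* Hairpin scoring is base-pair counting, not free energy.
* The CR composite score's equal weighting is a convention, not a fitted
  model; all components are exposed for re-weighting.
* GenBank writing, multi-record genomes and de-novo annotation are not
  supported.
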