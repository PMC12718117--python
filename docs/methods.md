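# Methods

## Model of alternative translation initiation

`isoselect` treats a gene's proteome as the set of proteoforms produced by
initiating translation at different codons of the same (spliced) mRNA.  Two
pair types are modelled:

* **Truncation pair** — an in-frame AUG downstream of the annotated start,
  before the annotated stop.  Because it is in frame and inside the CDS,
  translation from it necessarily terminates at the annotated stop, so the
  truncated proteoform is an exact suffix of the annotated one.
* **Extension pair** — an in-frame start (AUG or near-cognate) upstream of
  the annotated start with no in-frame stop in between; the annotated
  proteoform is an exact suffix of the extended one.

Upstream sites that are out of frame, or in frame but separated from the
annotated start by an in-frame stop, are upstream ORFs (uORFs) and do not
form pairs.  When the same genomic site is a uORF on one transcript of a
gene and an extension on another (different 5′ exon content), it is
finalised as a uORF and excluded, so only unambiguous extensions are paired.
Downstream out-of-frame sites are recorded as `other`.

Assumptions: one spliced transcript carries both proteoforms of a pair; the
standard nuclear genetic code; near-cognate initiation delivers the
initiator Met (so all proteoforms begin with M); no readthrough,
selenocysteine, or organellar codes.

## Site selection and pairing

Initiation efficiency is footprint reads at the site divided by mRNA
abundance.  Per gene and ORF type the most efficient site is kept; exact
ties go to the more 5′ site in transcript coordinates, then the smallest
transcript id (the selection is therefore order-invariant, which a test
checks directly).  Selection is joint across a gene's transcripts.  Each
gene contributes at most one truncation and one extension pair.  Sequence
generation uses the most highly expressed transcript on which the selected
site is usable.  Transcripts whose CDS length is not a multiple of 3, or
whose annotated start is not ATG (configurable), are flagged and excluded
from pairing rather than dropped.

## Coordinates and notation

Internally all coordinates are 0-based half-open; GTF/GFF3 (1-based
inclusive), BED/bedGraph (0-based half-open) and VCF (1-based) convert at
the file boundary.  CDS positions use HGVS-style numbering (c.1 = A of the
annotated start, negative upstream, no c.0), so printed clinical positions
like c.88 or c.128 can be used directly.  Protein changes are written in
three-letter HGVS style; frameshifts as `p.Gln25Hisfs*6`, where the number
after `*` counts codons from the first changed residue to the new stop
inclusive (the older `p.Gln25His*6` style is the same quantity).

Variants are normalised to a left-aligned minimal representation by
trimming shared prefixes/suffixes.  HGVS's 3′-shifting rule for indels is
deliberately **not** applied — a documented deviation chosen so that the
genomic footprint used for start-codon overlap is the literal input span.

## Per-isoform consequences

A variant is applied in transcript space (exon-boundary-spanning variants
are unsupported and rejected per transcript), giving a mutated spliced
sequence and a position map.  For each isoform the mutated sequence is
translated from the position-mapped start and compared to wild type, in
this order:

1. start codon deleted or changed → `start_loss`;
2. identical protein → `upstream_of_start` (edit strictly 5′ of the start),
   `synonymous` (in the ORF), or `non_coding` (3′ of the stop / intronic);
3. frame-disrupting length change → `frameshift`;
4. mutant a proper prefix of wild type → `nonsense`;
5. wild type a proper prefix of the mutant → `stop_loss`;
6. anything else → `missense`.

Protein-altering in-frame indels have no slot of their own in this
vocabulary and are reported as `missense` (non-truncating alteration); a
frameshift so close to the stop that the protein is unchanged is reported
as `synonymous`.  Both conventions are shared with the test oracle and are
visible in the p. notation.

## ISA categories

Per (variant, pair), with "long"/"short" denoting the isoform with the 5′-
and 3′-most start respectively:

* `alternative_start_loss` — the variant overlaps and changes the
  alternative start codon.  Restricted to AUG alternative starts by
  default; `--near-cognate-start-loss` extends it (flagged separately).  A
  near-cognate start hit under the default policy degrades to `shared` if
  the annotated protein is also altered, else `outside_pair_scope`.
* `annotated_only_LoF` — nonsense/frameshift on the long isoform of a
  truncation pair with the short isoform's protein untouched (the variant
  necessarily lies strictly 5′ of the short start).  The analogous call on
  extension pairs is emitted as `alternative_only_LoF` and flagged as the
  extension generalisation.
* `isoform_specific_missense` — missense confined to the inter-start
  region.
* `shared` — both proteins affected (variant at/after the short start).
* `outside_pair_scope` — everything else (upstream of both starts,
  synonymous, intronic/UTR).

A variant destroying the *annotated* start codon is isoform-selective in
spirit but is not given its own category; it lands in `outside_pair_scope`
with the `start_loss` consequence preserved in the per-isoform calls — a
known limitation of the category vocabulary.  Protein-preserving variants
inside a Kozak window (−6..+4 of either start) carry an advisory flag, not
a category, because no quantitative rule for Kozak-mediated selectivity is
defined.

## Localization comparison

The predictor is an external black box behind a file contract
(`proteoform_id`, comma-separated labels from a fixed 10-compartment
vocabulary, one probability column per compartment).  Label sets are taken
from the predictor's multi-label output; a 0.5 threshold applies only when
labels are absent.  Transition counting: identical label sets produce one
self-transition per label ("no transitions across organelles"); otherwise
every (annotated label, alternative label) combination is one transition,
including for partially overlapping sets — so a pair contributes |A|·|B|
transitions when A≠B and |A| when A=B.  Differential calls merge Nucleus
and Cytoplasm first by default, reflecting how poorly predictors separate
those compartments; `average_nucleocytoplasmic` provides the corresponding
probability summary (mean of the two).

The built-in `fixture_predictor` is a deterministic rule on the 15 residues
after the initiator Met (≥6 R → Mitochondrion, ≥6 K → Nucleus, ≥12
hydrophobic → ER signal, else Cytoplasm).  It exists so the pipeline is
testable offline and recognises exactly the sentinel motifs the synthetic
generator plants; it is not a sequence-analysis method and says nothing
about real proteins.

## Conservation and Kozak

Start-codon conservation is the arithmetic mean of a PhyloP-style track
over the codon's 3 bases; if any base is unscored the summary is flagged
incomplete and the partial mean withheld.  Near-cognate starts carry a note
that codon-identity turnover between species (CUG→UUG) can depress
per-base conservation even when usage is conserved; no correction is
applied.  Kozak strength uses the standard heuristic — purine at −3 and G
at +4 → strong, exactly one → adequate, neither → weak; windows truncated
by transcript ends are flagged and left unclassified.  Kozak optimisation
replaces −6..−1 with `GCCACC` and keeps the +4 base so the protein is
unchanged; it is idempotent and touches at most 6 positions.

Masking-construct tags: the FLAG-S tag is
`MDYKDDDDKGKETAAAKFERQHMDSGGT`; the 2×NLS constant is a doubled SV40 NLS
(`MPKKKRKVPKKKRKV`), a synthetic stand-in chosen because the classic SV40
heptapeptide is the field's default NLS.

## Synthetic data generator

Genes are designed in transcript space — 5′ UTR codon slots, a CDS of
codons, a 3′ UTR — from a "neutral" codon alphabet (G,S,T,N,Q,D,E,P,H,Y:
stop-free, Met/Arg/Lys-free, at most mildly hydrophobic), then exonised by
inserting GT..AG introns at cut points that avoid start codons, planted TIS
and variant footprints, and reverse-complemented for minus-strand genes.
Frame and stop invariants therefore hold *by construction* wherever the
truth assumes them; no rejection sampling is needed.

Defaults describe the emulated cohort: 12 genes (the oracle-agreement run
uses 52), half on each strand, 1–4 exons, 60–120 CDS codons, alternative
truncation starts at codons 18–40, extensions of 10–24 codons (half
near-cognate CUG), uORFs in ~30% of genes, and a differential localization
motif planted in ~60% of pairs.  Ten variant designs are planted per
truncation pair, covering every category plus the boundary cases (first and
last base of the alternative start codon, a 1-nt insertion immediately 5′
of it) and an intronic control; extension pairs get a LoF inside the
extension and a start-codon hit.  One pair's conservation track is emitted
with a missing base to exercise the incomplete-data path, and one
two-transcript gene realises the uORF-vs-extension ambiguity.

What the generator does **not** emulate: realistic codon usage and GC
content, overlapping genes, splice-site variation, sequencing noise in TIS
calls, and real localization signals (sentinel motifs stand in for them).
Passing tests therefore demonstrate the correctness of the coordinate
arithmetic, classification logic and counting rules — not predictive
performance on biological sequences.

## Numerical and degenerate-input choices

All tie-breaks are lexicographic and documented; every writer sorts its
rows, so identical inputs give byte-identical outputs.  Division guards:
initiation efficiency requires positive mRNA abundance.  Codons containing
N translate as X.  Translation hitting the transcript end without a stop is
flagged "runs off" and the frameshift stop offset becomes `fs*?`.  Variants
whose reference allele disagrees with the genome are rejected with a log
message rather than an error.

## Problem sizes

The test suite runs a 12-gene cohort for module tests, a 52-gene cohort
with 1,000 random variants for the oracle-equivalence check, and three
12-gene cohorts for the end-to-end determinism check; the acceptance script
repeats the same computations from a command-line seed.  These sizes were
chosen to exercise every code path (both strands, 1–4 exons, all variant
designs) while keeping a full run in the low seconds.
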