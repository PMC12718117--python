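# isoselect

Isoform-selective allele analysis from alternative translation initiation
sites.

## The problem

Many human mRNAs initiate translation at more than one start codon.
Downstream in-frame AUGs produce N-terminally **truncated** proteoforms;
upstream in-frame starts (often near-cognate codons such as CUG or GUG)
produce N-terminal **extensions**.  Because N-terminal targeting signals
(mitochondrial presequences, signal peptides, NLSs) live at the very front
of a protein, the two proteoforms of such a pair frequently go to different
compartments.

This has direct consequences for variant interpretation.  A nonsense or
frameshift variant that lies *between* the two start codons eliminates only
the longer proteoform — scanning ribosomes still initiate at the downstream
start, so the shorter isoform is untouched.  Conversely, a variant that is a
bland missense change on the annotated protein (e.g. Met→Leu at an internal
methionine) can abolish an alternative start codon and silently delete an
entire isoform.  Standard gene-level consequence annotation misses both
situations; `isoselect` makes them explicit.  Its users are genomicists and
clinical-variant analysts who have a transcript annotation, a catalog of
empirically called translation initiation sites (TIS; e.g. from
harringtonine ribosome profiling), and a variant table.

## What it computes

Given a genome FASTA, a GTF/GFF3 annotation, and a BED-like TIS table
(codon interval, codon identity, ribosome-footprint reads, mRNA abundance):

1. **ORF typing** — each TIS is classified relative to the annotated CDS as
   `annotated`, `truncation` (downstream, in frame, sharing the stop),
   `extension` (upstream, in frame, no intervening in-frame stop), `uORF`,
   or `other`.  A site that reads as a uORF on one transcript of a gene but
   as an extension on another is finalised as a uORF and excluded, so only
   unambiguous extensions form pairs.
2. **Pair assembly** — per gene and ORF type the strongest site by
   initiation efficiency (footprint reads / mRNA abundance) defines at most
   one truncation and one extension pair; sequences are generated on the
   most highly expressed transcript carrying the site.
3. **Proteoform generation** — strand-aware spliced translation with
   initiator-Met for near-cognate starts; FASTA output keyed by stable
   proteoform IDs, ready for external localization predictors.  Differential
   N-terminal regions and N-terminal masking constructs (FLAG-S, 2×NLS
   prepends) are also emitted.
4. **ISA classification** — every variant is applied to the spliced
   transcript, translated from each isoform's position-mapped start, and the
   per-isoform consequences (HGVS-style c. and p. notation) combine into an
   isoform-selective allele category:
   `annotated_only_LoF`, `alternative_only_LoF` (extension pairs),
   `alternative_start_loss`, `isoform_specific_missense`, `shared`, or
   `outside_pair_scope`.
5. **Localization transitions** — predictions for the two isoforms of a
   pair (external predictor output, or a built-in deterministic fixture
   predictor for offline testing) are compared: identical label sets yield
   one self-transition per label; differing sets yield the full cross
   product of (annotated label → alternative label).  Nucleus and cytosol
   are merged by default before calling a pair differential, since
   predictors separate the two poorly.
6. **Start-codon conservation and Kozak context** — per-start 3-nt mean of a
   PhyloP-style track, with the mean withheld when any base is unscored, and
   the standard Kozak heuristic (purine at −3, G at +4; optimisation
   rewrites −6..−1 to `GCCACC`, keeping +4).

A deterministic synthetic-data generator (`isoselect.simulate`) produces
genomes, annotations, TIS tables, VCFs and conservation tracks with full
ground truth, so the entire pipeline is testable without any download.

## Worked example

The bundled micro-fixture mirrors two published-style cases: a gene with an
alternative AUG at codon 30 (c.88–90) and one with an alternative AUG at
codon 52.

```python
import isoselect as iso

bundle = iso.trnt1_like_fixture()
records = iso.classify_catalog(bundle.tis_records, bundle.transcripts, bundle.genome)
pairs = {p.gene_id: p for p in iso.build_isoform_pairs(records, bundle.transcripts, bundle.genome)}

for gene, pair in sorted(pairs.items()):
    ann, alt = iso.build_pair_proteoforms(pair, bundle.transcripts, bundle.genome)
    loc_a = iso.fixture_predictor(ann.sequence).labels
    loc_b = iso.fixture_predictor(alt.sequence).labels
    print(f"{gene}: alternative start at codon {pair.alt_codon_index} (c.{pair.alt_c}), "
          f"annotated {len(ann.sequence)} aa -> {set(loc_a)}, "
          f"truncated {len(alt.sequence)} aa -> {set(loc_b)}")

for v in bundle.variants:
    pair = pairs[v.variant_id.split("_")[0]]
    call = iso.classify_isa(v, pair, bundle.transcripts, bundle.genome)
    ann = call.consequences["annotated"]
    alt = call.consequences["alternative"]
    print(f"{ann.c_notation:<12} {call.category:<26} "
          f"annotated={ann.consequence}/{ann.p_notation}  alternative={alt.consequence}")
```

prints

```
NAXEL: alternative start at codon 52 (c.154), annotated 149 aa -> {'Mitochondrion'}, truncated 98 aa -> {'Cytoplasm'}
TRNT1L: alternative start at codon 30 (c.88), annotated 119 aa -> {'Mitochondrion'}, truncated 90 aa -> {'Nucleus'}
c.74_75insTGGCAGCACCAACTAAGCAG annotated_only_LoF         annotated=frameshift/p.Gln25Hisfs*6  alternative=upstream_of_start
c.88A>T      alternative_start_loss     annotated=missense/p.Met30Leu  alternative=start_loss
c.88A>G      alternative_start_loss     annotated=missense/p.Met30Val  alternative=start_loss
c.128C>A     annotated_only_LoF         annotated=nonsense/p.Ser43Ter  alternative=upstream_of_start
c.16C>T      isoform_specific_missense  annotated=missense/p.Arg6Trp  alternative=upstream_of_start
```

Reading the first line of variant output: a 20-nt insertion after c.74
frameshifts the annotated protein from Gln25 (new stop 6 codons on) but lies
5′ of the codon-30 start, so the truncated isoform is untouched — an
annotated-only loss of function.  The c.88A>T change is an unremarkable
Met30Leu missense on the annotated protein but destroys the alternative
start codon, eliminating the short isoform.

## Command line

```sh
isoselect simulate --seed 3 --out-dir fix/          # synthetic inputs + truth
isoselect pairs       --genome fix/genome.fa --annotation fix/annotation.gtf --tis fix/tis.bed --out pairs.tsv
isoselect proteins    ... --out proteoforms.fa      # predictor input
isoselect variants    ... --variants fix/variants.vcf --out-prefix isa
isoselect localize    ... --fixture-predictor --out-prefix loc
isoselect transitions ... --fixture-predictor --out-prefix trans
isoselect conserve    ... --bedgraph fix/conservation.bedgraph --out cons.tsv
isoselect report --isa-summary isa_summary.json --localization loc.tsv \
                 --transitions trans.json --out-prefix report
```

The stages are file-based so an external predictor (DeepLoc-class tooling)
can be run on `proteoforms.fa` and its table handed to `localize`/
`transitions` via `--predictions`.  Proteoform FASTA headers follow the
fixed grammar `gene|pair_type|role start_codon=XXX c_start=N transcript=TID`.

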