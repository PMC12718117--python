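"""Deterministic synthetic genomes, annotations, TIS calls, variants and
conservation tracks with exhaustive ground truth.

Each simulated gene is designed in transcript space — 5' UTR codon slots, a
CDS of codons, planted alternative start codons, localization sentinel
motifs and variants — and then assembled into a genomic sequence by
inserting introns and (for minus-strand genes) reverse-complementing the
block.  Because every planted feature is placed codon-wise from a stop-free
codon alphabet, frame and stop invariants hold by construction wherever the
ground truth assumes them.

The generator's outputs re-parse through the package's own readers (FASTA,
GTF, BED, VCF, bedGraph), and the bundled truth records the expected ORF
types, pair structures, per-variant ISA categories and per-pair
localization labels under the built-in fixture predictor.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSequence, TranscriptModel, reverse_complement
from .localization import differential_call, fixture_predictor
from .proteoform import translate_cds
from .tis import TISRecord, write_tis_table
from .variants import VariantRecord

# codons encoding unremarkable residues (G,S,T,N,Q,D,E,P,H,Y): no stops, no
# Met, no Arg/Lys, at most mildly hydrophobic — keeps planted localization
# motifs unambiguous and regions stop-free in frame
_NEUTRAL = ("GGC", "AGC", "ACC", "AAC", "CAG", "GAT", "GAG", "CCA", "CAC", "TAC")
_MITO_MOTIF = ("CGT", "CGC", "CGA", "CGG", "CGT", "CGC")  # R x 6
_NLS_MOTIF = ("AAA", "AAG", "AAA", "AAG", "AAA", "AAG")  # K x 6
_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a gene set in which most genes carry a downstream
    in-frame truncation start, a third carry an upstream extension start
    (often near-cognate, as observed for CUG extensions), and upstream ORFs
    are common; a little over half of the pairs are planted with a
    differential localization signal.
    """

    seed: int = 0
    n_genes: int = 12
    p_minus_strand: float = 0.5
    exon_range: tuple[int, int] = (1, 4)
    frac_truncation: float = 0.8
    frac_extension: float = 0.35
    frac_uorf: float = 0.3
    frac_near_cognate_extension: float = 0.5
    p_differential_localization: float = 0.6
    utr5_codons: tuple[int, int] = (12, 20)
    cds_codons: tuple[int, int] = (60, 120)
    alt_codon_index: tuple[int, int] = (18, 40)
    extension_codons: tuple[int, int] = (10, 24)
    intron_length: tuple[int, int] = (30, 80)
    utr3_length: int = 36
    include_ambiguous_gene: bool = True
    incomplete_conservation_gene: bool = True
    # variants planted per truncation pair, keyed by planted design
    variant_plan: dict = field(
        default_factory=lambda: {
            "nonsense_inter_start": 1,
            "frameshift_inter_start": 1,
            "insertion_before_alt_start": 1,
            "alt_start_first_base": 1,
            "alt_start_last_base": 1,
            "missense_inter_start": 1,
            "shared_downstream": 1,
            "synonymous_inter_start": 1,
            "upstream_utr": 1,
            "intronic": 1,
        }
    )

    def validate(self) -> None:
        for name in ("frac_truncation", "frac_extension", "frac_uorf",
                     "frac_near_cognate_extension", "p_differential_localization",
                     "p_minus_strand"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if any(n < 0 for n in self.variant_plan.values()):
            raise SimulationError("negative variant counts")
        if self.alt_codon_index[0] < 18:
            raise SimulationError("alternative start codon index must be >= 18")
        if self.cds_codons[0] < self.alt_codon_index[0] + 14:
            raise SimulationError(
                "CDS too short for the requested alternative start codon index"
            )
        if self.n_genes < 1:
            raise SimulationError("need at least one gene")


@dataclass
class SimBundle:
    """In-memory simulation outputs plus the ground truth."""

    genome: GenomeSequence
    transcripts: dict[str, TranscriptModel]
    tis_records: list[TISRecord]
    variants: list[VariantRecord]
    conservation_rows: list[tuple[str, int, int, float]]
    truth: dict

    def write(self, outdir) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "annotation": os.path.join(outdir, "annotation.gtf"),
            "tis": os.path.join(outdir, "tis.bed"),
            "variants": os.path.join(outdir, "variants.vcf"),
            "conservation": os.path.join(outdir, "conservation.bedgraph"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        _write_fasta(self.genome, paths["genome"])
        _write_gtf(self.transcripts, paths["annotation"])
        write_tis_table(self.tis_records, paths["tis"])
        _write_vcf(self.variants, self.genome, paths["variants"])
        with open(paths["conservation"], "w") as fh:
            for contig, s, e, v in sorted(self.conservation_rows):
                fh.write(f"{contig}\t{s}\t{e}\t{v:.4f}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# writers


def _write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in genome.contigs():
            seq = genome.fetch(contig, 0, genome.length(contig))
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _cds_blocks(t: TranscriptModel, include_stop=True, stop_only=False):
    if stop_only:
        return t.project_to_genomic(t.cds_tend - 3, t.cds_tend)
    hi = t.cds_tend if include_stop else t.cds_tend - 3
    return t.project_to_genomic(t.cds_tstart, hi)


def _write_gtf(transcripts: dict[str, TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(transcripts):
            t = transcripts[tid]
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'expression "{t.expression:g}";'
            )
            span = (t.exons[0][0] + 1, t.exons[-1][1])

            def row(ftype, s1, e1):
                fh.write(
                    f"{t.contig}\tsim\t{ftype}\t{s1}\t{e1}\t.\t{t.strand}\t.\t{attrs}\n"
                )

            row("transcript", span[0], span[1])
            for s, e in t.exons:
                row("exon", s + 1, e)
            if t.is_coding:
                for s, e in _cds_blocks(t, include_stop=False):
                    row("CDS", s + 1, e)
                for s, e in _cds_blocks(t, stop_only=True):
                    row("stop_codon", s + 1, e)


def _write_vcf(variants: list[VariantRecord], genome: GenomeSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in genome.contigs():
            fh.write(f"##contig=<ID={contig},length={genome.length(contig)}>\n")
        fh.write(
            '##INFO=<ID=CLNSIG,Number=1,Type=String,'
            'Description="Clinical significance">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.ref, v.alt)):
            info = f"CLNSIG={v.significance}" if v.significance else "."
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.variant_id or '.'}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# gene design in transcript space


@dataclass
class _PlantedVariant:
    design: str
    t_lo: int  # transcript position of the first replaced base (insertions:
    # the insertion point; -1 for intronic placements resolved later)
    ref_t: str  # transcript-strand reference bases (empty for insertion)
    alt_t: str  # transcript-strand replacement (empty for deletion)
    per_pair: dict  # pair_type -> {"category", "annotated", "alternative"}
    expect_p: dict = field(default_factory=dict)  # role -> exact p. string


@dataclass
class _GeneDesign:
    gene_id: str
    strand: str
    utr5: list[str]
    cds: list[str]
    utr3: str
    alt_codon_index: int | None = None
    alt2_codon_index: int | None = None  # weaker second truncation site
    ext_slot: int | None = None
    ext_codon: str = "ATG"
    uorf_tpos: int | None = None
    planted: list[_PlantedVariant] = field(default_factory=list)
    localization: dict = field(default_factory=dict)

    @property
    def tx(self) -> str:
        return "".join(self.utr5) + "".join(self.cds) + self.utr3

    @property
    def cds_tstart(self) -> int:
        return 3 * len(self.utr5)

    @property
    def cds_tend(self) -> int:
        return self.cds_tstart + 3 * len(self.cds)

    def codon_tpos(self, index_1based: int) -> int:
        return self.cds_tstart + 3 * (index_1based - 1)


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _intron(rng, cfg: SimConfig) -> str:
    n = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
    return "GT" + _rand_seq(rng, n - 4) + "AG"


def _neutral_codons(rng, n: int) -> list[str]:
    return [_NEUTRAL[i] for i in rng.integers(0, len(_NEUTRAL), size=n)]


def _protein(codon_list: list[str], start_index_1based: int = 1) -> str:
    seq, _ = translate_cds("".join(codon_list[start_index_1based - 1 :]) + "TAA")
    return seq


def _design_gene(rng, cfg: SimConfig, gene_id: str) -> _GeneDesign:
    strand = "-" if rng.random() < cfg.p_minus_strand else "+"
    n_cod = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    m = int(rng.integers(cfg.utr5_codons[0], cfg.utr5_codons[1] + 1))
    d = _GeneDesign(
        gene_id=gene_id,
        strand=strand,
        utr5=_neutral_codons(rng, m),
        cds=_neutral_codons(rng, n_cod),
        utr3="TAA" + _rand_seq(rng, cfg.utr3_length - 3),
    )
    d.cds[0] = "ATG"
    d.cds[-1] = "TAA"

    has_trunc = rng.random() < cfg.frac_truncation
    has_ext = rng.random() < cfg.frac_extension
    has_uorf = rng.random() < cfg.frac_uorf

    if has_trunc:
        k_hi = min(cfg.alt_codon_index[1], n_cod - 14)
        k = int(rng.integers(cfg.alt_codon_index[0], k_hi + 1))
        d.alt_codon_index = k
        d.cds[k - 1] = "ATG"
        if rng.random() < 0.5:  # weaker second truncation site
            d.alt2_codon_index = k + 10
            d.cds[k + 9] = "ATG"
    if has_ext:
        if m < cfg.extension_codons[0] + 3:  # widen the UTR to fit the extension
            m = cfg.extension_codons[0] + 3
            d.utr5 = _neutral_codons(rng, m)
        e_hi = min(cfg.extension_codons[1], m - 3)
        n_ext = int(rng.integers(cfg.extension_codons[0], e_hi + 1))
        d.ext_slot = m - n_ext
        d.ext_codon = (
            "CTG" if rng.random() < cfg.frac_near_cognate_extension else "ATG"
        )
        d.utr5[d.ext_slot] = d.ext_codon
    if has_uorf:
        # out-of-frame upstream AUG written across two free UTR slots
        limit = (d.ext_slot if d.ext_slot is not None else len(d.utr5)) - 1
        if limit >= 3:
            slot = int(rng.integers(1, limit - 1))
            d.utr5[slot], d.utr5[slot + 1] = "CAT", "GGC"  # ATG at frame offset +1
            d.uorf_tpos = 3 * slot + 1

    # localization design
    k = d.alt_codon_index
    if k is not None:
        if rng.random() < cfg.p_differential_localization:
            scheme = ["mito_cyto", "mito_nuc"][int(rng.integers(0, 2))]
        else:
            scheme = ["cyto_nuc", "none"][int(rng.integers(0, 2))]
        if scheme in ("mito_cyto", "mito_nuc"):
            d.cds[1:7] = list(_MITO_MOTIF)
        if scheme in ("mito_nuc", "cyto_nuc"):
            d.cds[k : k + 6] = list(_NLS_MOTIF)
        d.localization["truncation"] = scheme
    if d.ext_slot is not None:
        n_ext = len(d.utr5) - d.ext_slot
        if rng.random() < cfg.p_differential_localization and n_ext >= 17:
            d.utr5[d.ext_slot + 1 : d.ext_slot + 7] = list(_MITO_MOTIF)
            d.localization["extension"] = "ext_mito"
        else:
            d.localization["extension"] = "none"
    return d


def _truth_truncation(d: _GeneDesign, category, ann, alt) -> dict:
    """Truth for a variant planted relative to the truncation pair.

    CDS variants lie downstream of both the extension start and the annotated
    start, so on a coexisting extension pair a protein-changing call is
    shared and a silent one out of scope.
    """
    per = {"truncation": {"category": category, "annotated": ann, "alternative": alt}}
    if d.ext_slot is not None:
        if ann == "synonymous":
            per["extension"] = {"category": "outside_pair_scope",
                                "annotated": "synonymous",
                                "alternative": "synonymous"}
        else:
            per["extension"] = {"category": "shared", "annotated": ann,
                                "alternative": ann}
    return per


def _truth_extension(d: _GeneDesign, category, ann, alt) -> dict:
    per = {"extension": {"category": category, "annotated": ann, "alternative": alt}}
    if d.alt_codon_index is not None:
        per["truncation"] = {"category": "outside_pair_scope",
                             "annotated": "upstream_of_start",
                             "alternative": "upstream_of_start"}
    return per


def _truth_all(d: _GeneDesign, category, ann, alt) -> dict:
    per = {}
    if d.alt_codon_index is not None:
        per["truncation"] = {"category": category, "annotated": ann,
                             "alternative": alt}
    if d.ext_slot is not None:
        per["extension"] = {"category": category, "annotated": ann,
                            "alternative": alt}
    return per


def _plant_variants(rng, cfg: SimConfig, d: _GeneDesign) -> None:
    """Plant the configured variant designs on a gene's truncation pair,
    reserving codon slots so no two variants touch the same codon."""
    k = d.alt_codon_index
    if k is None:
        return
    reserved = {1, k, len(d.cds)} | set(range(2, 8)) | set(range(k + 1, k + 7))
    if d.alt2_codon_index is not None:
        reserved.add(d.alt2_codon_index)
    free = [i for i in range(9, k - 1) if i not in reserved]
    rng.shuffle(free)
    free = list(free)

    def take() -> int:
        if not free:
            raise SimulationError(
                f"{d.gene_id}: inter-start region too short for the variant plan"
            )
        return int(free.pop())

    plan = cfg.variant_plan
    for _ in range(plan.get("nonsense_inter_start", 0)):
        j = take()
        d.cds[j - 1] = "TCA"  # Ser codon one substitution away from TAA
        d.planted.append(
            _PlantedVariant("nonsense_inter_start", d.codon_tpos(j) + 1, "C", "A",
                            _truth_truncation(d, "annotated_only_LoF",
                                              "nonsense", "upstream_of_start"))
        )
    for _ in range(plan.get("frameshift_inter_start", 0)):
        j = take()
        d.planted.append(
            _PlantedVariant("frameshift_inter_start", d.codon_tpos(j),
                            d.cds[j - 1][0], "",
                            _truth_truncation(d, "annotated_only_LoF",
                                              "frameshift", "upstream_of_start"))
        )
    for _ in range(plan.get("insertion_before_alt_start", 0)):
        d.planted.append(  # 1-nt insertion immediately 5' of the alt start codon
            _PlantedVariant("insertion_before_alt_start", d.codon_tpos(k), "", "G",
                            _truth_truncation(d, "annotated_only_LoF",
                                              "frameshift", "upstream_of_start"))
        )
    for _ in range(plan.get("alt_start_first_base", 0)):
        d.planted.append(  # ATG -> CTG: annotated Met->Leu, alternative start lost
            _PlantedVariant("alt_start_first_base", d.codon_tpos(k), "A", "C",
                            _truth_truncation(d, "alternative_start_loss",
                                              "missense", "start_loss"))
        )
    for _ in range(plan.get("alt_start_last_base", 0)):
        d.planted.append(  # ATG -> ATA: annotated Met->Ile, alternative start lost
            _PlantedVariant("alt_start_last_base", d.codon_tpos(k) + 2, "G", "A",
                            _truth_truncation(d, "alternative_start_loss",
                                              "missense", "start_loss"))
        )
    for _ in range(plan.get("missense_inter_start", 0)):
        j = take()
        d.cds[j - 1] = "GAT"  # Asp -> His via G>C at the first base
        d.planted.append(
            _PlantedVariant("missense_inter_start", d.codon_tpos(j), "G", "C",
                            _truth_truncation(d, "isoform_specific_missense",
                                              "missense", "upstream_of_start"))
        )
    for _ in range(plan.get("shared_downstream", 0)):
        lo = k + 12 if d.alt2_codon_index is not None else k + 8
        j = int(rng.integers(lo, len(d.cds) - 2))
        d.cds[j - 1] = "GAG"  # Glu -> Gln via G>C: missense on both isoforms
        d.planted.append(
            _PlantedVariant("shared_downstream", d.codon_tpos(j), "G", "C",
                            _truth_truncation(d, "shared", "missense", "missense"))
        )
    for _ in range(plan.get("synonymous_inter_start", 0)):
        j = take()
        d.cds[j - 1] = "GGC"  # Gly GGC -> GGA, silent on both isoforms
        d.planted.append(
            _PlantedVariant("synonymous_inter_start", d.codon_tpos(j) + 2, "C", "A",
                            _truth_truncation(d, "outside_pair_scope",
                                              "synonymous", "upstream_of_start"))
        )
    for _ in range(plan.get("upstream_utr", 0)):
        hi = (3 * d.ext_slot - 3) if d.ext_slot is not None else d.cds_tstart - 8
        uorf_block = (
            range(d.uorf_tpos - 1, d.uorf_tpos + 4) if d.uorf_tpos is not None else ()
        )
        candidates = [t for t in range(1, hi) if t not in uorf_block]
        if not candidates:
            continue
        t = int(candidates[int(rng.integers(0, len(candidates)))])
        base = d.tx[t]
        d.planted.append(
            _PlantedVariant("upstream_utr", t, base, "A" if base != "A" else "G",
                            _truth_all(d, "outside_pair_scope",
                                       "upstream_of_start", "upstream_of_start"))
        )
    for _ in range(plan.get("intronic", 0)):
        d.planted.append(
            _PlantedVariant("intronic", -1, "", "",
                            _truth_all(d, "outside_pair_scope",
                                       "non_coding", "non_coding"))
        )
    # extension-pair variants: a LoF inside the extension and a start overlap
    if d.ext_slot is not None:
        slots = list(range(d.ext_slot + 8, len(d.utr5) - 1))
        if slots:
            s = int(slots[int(rng.integers(0, len(slots)))])
            d.utr5[s] = "TCA"
            d.planted.append(
                _PlantedVariant("ext_nonsense", 3 * s + 1, "C", "A",
                                _truth_extension(d, "alternative_only_LoF",
                                                 "upstream_of_start", "nonsense"))
            )
        base = d.utr5[d.ext_slot][0]
        cat = "alternative_start_loss" if d.ext_codon == "ATG" else "outside_pair_scope"
        d.planted.append(
            _PlantedVariant("ext_start_first_base", 3 * d.ext_slot, base,
                            "A" if base != "A" else "T",
                            _truth_extension(d, cat, "upstream_of_start",
                                             "start_loss"))
        )


# ---------------------------------------------------------------------------
# genomic assembly


def _choose_cuts(rng, d: _GeneDesign, n_exons: int) -> list[int]:
    if n_exons <= 1:
        return []
    tx_len = len(d.tx)
    protected: set[int] = set()

    def protect(lo: int, hi: int) -> None:
        protected.update(range(lo + 1, hi))

    protect(d.cds_tstart, d.cds_tstart + 3)
    protect(d.cds_tend - 3, d.cds_tend)
    for idx in (d.alt_codon_index, d.alt2_codon_index):
        if idx is not None:
            t = d.codon_tpos(idx)
            protect(t, t + 3)
    if d.ext_slot is not None:
        protect(3 * d.ext_slot, 3 * d.ext_slot + 3)
    if d.uorf_tpos is not None:
        protect(d.uorf_tpos, d.uorf_tpos + 3)
    for pv in d.planted:
        if pv.t_lo < 0:
            continue
        if pv.ref_t:
            protect(pv.t_lo - 1, pv.t_lo + len(pv.ref_t) + 1)
        else:
            protected.add(pv.t_lo)  # insertion anchor must stay intra-exon
    candidates = [p for p in range(15, tx_len - 15) if p not in protected]
    cuts: list[int] = []
    for _ in range(300):
        if len(cuts) == n_exons - 1 or not candidates:
            break
        p = int(candidates[int(rng.integers(0, len(candidates)))])
        if all(abs(p - c) >= 15 for c in cuts):
            cuts.append(p)
    return sorted(cuts)


def _assemble(rng, cfg: SimConfig, d: _GeneDesign):
    """Exonise the designed transcript: returns (forward-strand local genomic
    sequence, ascending exon intervals, ascending intron intervals)."""
    n_exons = int(rng.integers(cfg.exon_range[0], cfg.exon_range[1] + 1))
    cuts = _choose_cuts(rng, d, n_exons)
    tx = d.tx
    bounds = [0] + cuts + [len(tx)]
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    pos = 0
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        exons.append((pos, pos + b - a))
        parts.append(tx[a:b])
        pos += b - a
        if i < len(bounds) - 2:
            intron = _intron(rng, cfg)
            introns.append((pos, pos + len(intron)))
            parts.append(intron)
            pos += len(intron)
    g = "".join(parts)
    if d.strand == "-":
        L = len(g)
        g = reverse_complement(g)
        exons = sorted((L - e, L - s) for s, e in exons)
        introns = sorted((L - e, L - s) for s, e in introns)
    return g, exons, introns


def _build_model(d: _GeneDesign, contig: str, exons, expression: float) -> TranscriptModel:
    tid = f"{d.gene_id}.t1"
    probe = TranscriptModel(
        transcript_id=tid, gene_id=d.gene_id, contig=contig, strand=d.strand,
        exons=tuple(exons), cds_genomic=None, expression=expression,
    )
    g0 = probe.tpos_to_genomic(d.cds_tstart)
    g1 = probe.tpos_to_genomic(d.cds_tend - 1)
    return TranscriptModel(
        transcript_id=tid, gene_id=d.gene_id, contig=contig, strand=d.strand,
        exons=tuple(exons), cds_genomic=(min(g0, g1), max(g0, g1) + 1),
        expression=expression,
    )


# ---------------------------------------------------------------------------
# variant materialisation (requires the assembled genome)


def _materialise_variant(
    rng, genome: GenomeSequence, model: TranscriptModel, pv: _PlantedVariant,
    introns: list[tuple[int, int]],
) -> VariantRecord | None:
    contig = model.contig
    pathogenic = any(
        t["category"] in ("annotated_only_LoF", "alternative_only_LoF",
                          "alternative_start_loss")
        for t in pv.per_pair.values()
    )
    sig = "Pathogenic" if pathogenic else "Uncertain_significance"
    if pv.design == "intronic":
        if not introns:
            return None
        s, e = introns[int(rng.integers(0, len(introns)))]
        g = int(rng.integers(s + 6, e - 6))
        ref = genome.base(contig, g)
        return VariantRecord(contig=contig, pos=g + 1, ref=ref,
                             alt="A" if ref != "A" else "C", significance=sig)
    if pv.ref_t:
        gs = sorted(
            model.tpos_to_genomic(t) for t in range(pv.t_lo, pv.t_lo + len(pv.ref_t))
        )
        g_lo, g_hi = gs[0], gs[-1] + 1
        fwd_ref = genome.fetch(contig, g_lo, g_hi)
        fwd_alt = pv.alt_t if model.strand == "+" else reverse_complement(pv.alt_t)
        if not pv.alt_t:  # deletion: anchored VCF representation
            anchor = genome.base(contig, g_lo - 1)
            return VariantRecord(contig=contig, pos=g_lo, ref=anchor + fwd_ref,
                                 alt=anchor, significance=sig)
        return VariantRecord(contig=contig, pos=g_lo + 1, ref=fwd_ref,
                             alt=fwd_alt, significance=sig)
    # insertion before transcript position t_lo
    if model.strand == "+":
        anchor_g = model.tpos_to_genomic(pv.t_lo) - 1
        fwd_ins = pv.alt_t
    else:
        anchor_g = model.tpos_to_genomic(pv.t_lo)
        fwd_ins = reverse_complement(pv.alt_t)
    anchor = genome.base(contig, anchor_g)
    return VariantRecord(contig=contig, pos=anchor_g + 1, ref=anchor,
                         alt=anchor + fwd_ins, significance=sig)


# ---------------------------------------------------------------------------
# top-level simulation


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate a synthetic cohort with ground truth, reproducible from seed."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    designs = [_design_gene(rng, cfg, f"G{i + 1:03d}") for i in range(cfg.n_genes)]
    for d in designs:
        _plant_variants(rng, cfg, d)

    # assemble genes onto contigs
    contig_parts: dict[str, list[str]] = {}
    assembled = []  # (design, model, introns)
    genes_per_contig = 3
    for gi, d in enumerate(designs):
        contig = f"chr{gi // genes_per_contig + 1}"
        parts = contig_parts.setdefault(contig, [_rand_seq(rng, 50)])
        offset = sum(len(p) for p in parts)
        g_local, exons_local, introns_local = _assemble(rng, cfg, d)
        parts.append(g_local)
        parts.append(_rand_seq(rng, 50))
        exons = [(s + offset, e + offset) for s, e in exons_local]
        introns = [(s + offset, e + offset) for s, e in introns_local]
        expression = float(np.round(rng.uniform(5, 50), 2))
        assembled.append((d, _build_model(d, contig, exons, expression), introns))

    transcripts = {m.transcript_id: m for _, m, _ in assembled}
    amb_truth = None
    if cfg.include_ambiguous_gene:
        amb_truth = _add_ambiguous_gene(rng, contig_parts, transcripts)

    genome = GenomeSequence({c: "".join(p) for c, p in contig_parts.items()})

    tis_records: list[TISRecord] = []
    variants: list[VariantRecord] = []
    conservation_rows: list[tuple[str, int, int, float]] = []
    truth_genes: dict[str, dict] = {}
    truth_variants: list[dict] = []
    truth_conservation: dict[str, dict] = {}
    tallies: dict[str, int] = {}
    incomplete_pending = cfg.incomplete_conservation_gene

    for d, model, introns in assembled:
        gene_truth = _emit_tis_and_pairs(rng, d, model, tis_records)
        truth_genes[d.gene_id] = gene_truth
        # conservation per start codon
        for key, iv, high in _start_intervals(d, model, gene_truth):
            rows = [
                (model.contig, p, p + 1,
                 float(np.round(rng.uniform(*(1.8, 3.2) if high else (0.6, 2.4)), 3)))
                for p in range(iv[0], iv[1])
            ]
            if incomplete_pending and key.endswith("|truncation"):
                del rows[1]  # middle base unscored -> incomplete flag expected
                truth_conservation[key] = {"mean": None, "complete": False}
                incomplete_pending = False
            else:
                truth_conservation[key] = {
                    "mean": float(np.round(sum(r[3] for r in rows) / 3.0, 6)),
                    "complete": True,
                }
            conservation_rows.extend(rows)
        for pv in d.planted:
            rec = _materialise_variant(rng, genome, model, pv, introns)
            if rec is None:
                continue
            variants.append(rec)
            truth_variants.append(
                {"contig": rec.contig, "pos": rec.pos, "ref": rec.ref,
                 "alt": rec.alt, "gene": d.gene_id, "design": pv.design,
                 "per_pair": pv.per_pair}
            )
            for t in pv.per_pair.values():
                tallies[t["category"]] = tallies.get(t["category"], 0) + 1

    if amb_truth is not None:
        gene_id, gt, amb_tis = amb_truth
        truth_genes[gene_id] = gt
        tis_records.extend(amb_tis)

    truth = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "genes": truth_genes,
        "variants": sorted(
            truth_variants, key=lambda v: (v["contig"], v["pos"], v["ref"], v["alt"])
        ),
        "conservation": truth_conservation,
        "tallies": dict(sorted(tallies.items())),
    }
    return SimBundle(genome, transcripts, tis_records, variants,
                     sorted(conservation_rows), truth)


def _codon_interval(model: TranscriptModel, tpos: int) -> tuple[int, int]:
    g = sorted(model.tpos_to_genomic(tpos + i) for i in range(3))
    return g[0], g[2] + 1


def _start_intervals(d: _GeneDesign, model: TranscriptModel, gene_truth: dict):
    out = [(f"{d.gene_id}|annotated", _codon_interval(model, d.cds_tstart), True)]
    if d.alt_codon_index is not None:
        out.append(
            (f"{d.gene_id}|truncation",
             _codon_interval(model, d.codon_tpos(d.alt_codon_index)), False)
        )
    if d.ext_slot is not None:
        out.append(
            (f"{d.gene_id}|extension", _codon_interval(model, 3 * d.ext_slot), False)
        )
    return out


def _emit_tis_and_pairs(rng, d: _GeneDesign, model: TranscriptModel,
                        tis_records: list[TISRecord]) -> dict:
    tid = model.transcript_id
    gene_truth: dict = {
        "strand": d.strand,
        "transcript_id": tid,
        "n_exons": len(model.exons),
        "orf_types": {},
        "pairs": {},
    }

    def add_tis(tpos, codon, orf_type, reads, abund):
        s, e = _codon_interval(model, tpos)
        tis_records.append(
            TISRecord(gene_id=d.gene_id, transcript_id=tid, contig=model.contig,
                      strand=d.strand, codon_start=s, codon_end=e, codon=codon,
                      footprint_reads=reads, mrna_abundance=abund)
        )
        gene_truth["orf_types"][f"{model.contig}:{s}-{e}"] = orf_type

    abund = float(np.round(rng.uniform(5, 20), 2))
    add_tis(d.cds_tstart, "ATG", "annotated",
            float(np.round(rng.uniform(80, 160), 1)), abund)
    protein_ann = _protein(d.cds[:-1])

    if d.alt_codon_index is not None:
        k = d.alt_codon_index
        alt_reads = float(np.round(rng.uniform(30, 70), 1))
        add_tis(d.codon_tpos(k), "ATG", "truncation", alt_reads, abund)
        if d.alt2_codon_index is not None:
            add_tis(d.codon_tpos(d.alt2_codon_index), "ATG", "truncation",
                    float(np.round(alt_reads * 0.3, 1)), abund)
        protein_alt = _protein(d.cds[:-1], k)
        pa, pb = fixture_predictor(protein_ann), fixture_predictor(protein_alt)
        gene_truth["pairs"]["truncation"] = {
            "alt_codon_index": k,
            "alt_c": 3 * (k - 1) + 1,
            "inter_start_c": [1, 3 * (k - 1) + 1],
            "alt_codon": "ATG",
            "annotated_protein": protein_ann,
            "alternative_protein": protein_alt,
            "annotated_labels": sorted(pa.labels),
            "alternative_labels": sorted(pb.labels),
            "differential_collapsed": differential_call(pa, pb),
            "localization_scheme": d.localization.get("truncation", "none"),
        }
    if d.ext_slot is not None:
        n_ext = len(d.utr5) - d.ext_slot
        add_tis(3 * d.ext_slot, d.ext_codon, "extension",
                float(np.round(rng.uniform(10, 40), 1)), abund)
        protein_ext = _protein(d.utr5[d.ext_slot :] + d.cds[:-1])
        pa, pe = fixture_predictor(protein_ann), fixture_predictor(protein_ext)
        gene_truth["pairs"]["extension"] = {
            "extension_codons": n_ext,
            "alt_c": -3 * n_ext,
            "inter_start_c": [-3 * n_ext, 1],
            "alt_codon": d.ext_codon,
            "annotated_protein": protein_ann,
            "alternative_protein": protein_ext,
            "annotated_labels": sorted(pa.labels),
            "alternative_labels": sorted(pe.labels),
            "differential_collapsed": differential_call(pe, pa),
            "localization_scheme": d.localization.get("extension", "none"),
        }
    if d.uorf_tpos is not None:
        add_tis(d.uorf_tpos, "ATG", "uORF",
                float(np.round(rng.uniform(5, 25), 1)), abund)
    return gene_truth


def _add_ambiguous_gene(rng, contig_parts, transcripts):
    """A two-transcript gene whose shared upstream TIS is an extension on one
    transcript but a uORF (via a retained stop-carrying exon) on the other;
    the site must be finalised as a uORF and excluded from pairing."""
    gene_id = "GAMB"
    contig = "chrAmb"
    exonA_codons = ["GGC", "AGC", "ACC", "AAC", "CAG", "ATG", "GAT"]  # TIS at slot 5
    stopseg = "GGCTAAGGC"  # in-frame stop retained only in transcript 1
    exonB_utr = ["ACC", "AAC", "CAG", "GAT"]
    cds = ["ATG"] + [_NEUTRAL[i % 10] for i in range(28)] + ["TAA"]
    exonA = "".join(exonA_codons)
    exonB = "".join(exonB_utr) + "".join(cds) + "TAAGCTAGCGAT"
    i1, i2 = "GT" + _rand_seq(rng, 40) + "AG", "GT" + _rand_seq(rng, 40) + "AG"
    parts = contig_parts.setdefault(contig, [_rand_seq(rng, 50)])
    offset = sum(len(p) for p in parts)
    local = exonA + i1 + stopseg + i2 + exonB
    parts.append(local)
    parts.append(_rand_seq(rng, 50))

    def iv(lo, n):
        return (offset + lo, offset + lo + n)

    a = iv(0, len(exonA))
    s = iv(len(exonA) + len(i1), len(stopseg))
    b = iv(len(exonA) + len(i1) + len(stopseg) + len(i2), len(exonB))
    cds_lo = b[0] + len("".join(exonB_utr))
    cds_span = (cds_lo, cds_lo + 3 * len(cds))
    t1 = TranscriptModel(transcript_id=f"{gene_id}.t1", gene_id=gene_id,
                         contig=contig, strand="+", exons=(a, s, b),
                         cds_genomic=cds_span, expression=10.0)
    t2 = TranscriptModel(transcript_id=f"{gene_id}.t2", gene_id=gene_id,
                         contig=contig, strand="+", exons=(a, b),
                         cds_genomic=cds_span, expression=40.0)
    transcripts[t1.transcript_id] = t1
    transcripts[t2.transcript_id] = t2
    tis_pos = a[0] + 15  # slot 5 of exonA
    recs = [
        TISRecord(gene_id=gene_id, transcript_id=t2.transcript_id, contig=contig,
                  strand="+", codon_start=tis_pos, codon_end=tis_pos + 3,
                  codon="ATG", footprint_reads=30.0, mrna_abundance=10.0),
        TISRecord(gene_id=gene_id, transcript_id=t2.transcript_id, contig=contig,
                  strand="+", codon_start=cds_span[0], codon_end=cds_span[0] + 3,
                  codon="ATG", footprint_reads=100.0, mrna_abundance=10.0),
    ]
    gene_truth = {
        "strand": "+",
        "transcript_id": t2.transcript_id,
        "n_exons": 2,
        "ambiguous_uorf_extension": True,
        "orf_types": {
            f"{contig}:{tis_pos}-{tis_pos + 3}": "uORF",
            f"{contig}:{cds_span[0]}-{cds_span[0] + 3}": "annotated",
        },
        "pairs": {},
    }
    return gene_id, gene_truth, recs


# ---------------------------------------------------------------------------
# worked micro-fixture


def trnt1_like_fixture() -> SimBundle:
    """Two single-exon plus-strand genes mirroring published worked cases.

    ``TRNT1L``: alternative AUG at codon 30 (c.88-90), mitochondrial signal
    on the annotated N terminus, nuclear signal after Met30; variants: a
    20-nt insertion after c.74 (frameshift p.Gln25Hisfs*6, spares the
    truncated isoform), c.88A>T (p.Met30Leu / alternative start loss) and
    c.88A>G (p.Met30Val / alternative start loss).

    ``NAXEL``: alternative AUG at codon 52, Ser at codon 43; variants:
    c.128C>A (p.Ser43Ter, annotated-only LoF) and c.16C>T (p.Arg6Trp, an
    isoform-specific missense that degrades the planted mitochondrial
    signal).  The nucleotide sequences are synthetic; only the printed
    coordinate logic is mirrored.
    """
    spacer = "ACGT" * 10

    def make_cds(n, special: dict[int, str]) -> list[str]:
        cds = [_NEUTRAL[i % 10] for i in range(n)]
        cds[0] = "ATG"
        cds[-1] = "TAA"
        for idx1, codon in special.items():
            cds[idx1 - 1] = codon
        return cds

    utr5 = ["GGC", "AGC", "ACC", "AAC", "CAG", "GAT", "GAG", "CCA", "CAC", "TAC"]
    utr3 = "TAAGCTAGCGATCGATTACGCAGT"

    trnt1_cds = make_cds(
        120,
        {2: "CGT", 3: "CGC", 4: "CGA", 5: "CGG", 6: "CGT", 7: "CGC",
         25: "CAA", 30: "ATG",
         31: "AAA", 32: "AAG", 33: "AAA", 34: "AAG", 35: "AAA", 36: "AAG"},
    )
    naxe_cds = make_cds(
        150,
        {2: "CGT", 3: "CGC", 4: "CGA", 5: "CGG", 6: "CGG", 7: "CGC",
         43: "TCA", 52: "ATG"},
    )

    contig = "chrT"
    parts = [spacer]
    transcripts: dict[str, TranscriptModel] = {}
    layouts: dict[str, tuple[int, int]] = {}  # gene -> (tx_offset, cds_tstart)
    for gene_id, cds in (("TRNT1L", trnt1_cds), ("NAXEL", naxe_cds)):
        offset = sum(len(p) for p in parts)
        tx = "".join(utr5) + "".join(cds) + utr3
        parts.append(tx)
        parts.append(spacer)
        exons = ((offset, offset + len(tx)),)
        cds_lo = offset + 3 * len(utr5)
        transcripts[f"{gene_id}.t1"] = TranscriptModel(
            transcript_id=f"{gene_id}.t1", gene_id=gene_id, contig=contig,
            strand="+", exons=exons, cds_genomic=(cds_lo, cds_lo + 3 * len(cds)),
            expression=25.0,
        )
        layouts[gene_id] = (offset, cds_lo)

    genome = GenomeSequence({contig: "".join(parts)})

    def c2g(gene: str, c: int) -> int:
        return layouts[gene][1] + (c - 1)

    tis_records = []
    for gene, alt_codon_index, reads in (("TRNT1L", 30, 60.0), ("NAXEL", 52, 45.0)):
        cds_lo = layouts[gene][1]
        tis_records.append(
            TISRecord(gene_id=gene, transcript_id=f"{gene}.t1", contig=contig,
                      strand="+", codon_start=cds_lo, codon_end=cds_lo + 3,
                      codon="ATG", footprint_reads=120.0, mrna_abundance=10.0)
        )
        alt_lo = cds_lo + 3 * (alt_codon_index - 1)
        tis_records.append(
            TISRecord(gene_id=gene, transcript_id=f"{gene}.t1", contig=contig,
                      strand="+", codon_start=alt_lo, codon_end=alt_lo + 3,
                      codon="ATG", footprint_reads=reads, mrna_abundance=10.0)
        )

    ins20 = "TGGCAGCACCAACTAAGCAG"  # frameshifted codon 25 reads His, stop 6th
    v_ins = VariantRecord(
        contig=contig, pos=c2g("TRNT1L", 74) + 1,
        ref=genome.base(contig, c2g("TRNT1L", 74)),
        alt=genome.base(contig, c2g("TRNT1L", 74)) + ins20,
        significance="Pathogenic", variant_id="TRNT1L_c74ins20",
    )
    v_m30l = VariantRecord(contig=contig, pos=c2g("TRNT1L", 88) + 1, ref="A",
                           alt="T", significance="Pathogenic",
                           variant_id="TRNT1L_c88A_T")
    v_m30v = VariantRecord(contig=contig, pos=c2g("TRNT1L", 88) + 1, ref="A",
                           alt="G", significance="Uncertain_significance",
                           variant_id="TRNT1L_c88A_G")
    v_s43x = VariantRecord(contig=contig, pos=c2g("NAXEL", 128) + 1, ref="C",
                           alt="A", significance="Pathogenic",
                           variant_id="NAXEL_c128C_A")
    v_r6w = VariantRecord(contig=contig, pos=c2g("NAXEL", 16) + 1, ref="C",
                          alt="T", significance="Pathogenic",
                          variant_id="NAXEL_c16C_T")
    variants = [v_ins, v_m30l, v_m30v, v_s43x, v_r6w]

    conservation_rows = [
        (contig, p, p + 1, 2.5)
        for gene, k in (("TRNT1L", 30), ("NAXEL", 52))
        for start in (layouts[gene][1], layouts[gene][1] + 3 * (k - 1))
        for p in range(start, start + 3)
    ]

    truth = {
        "genes": {
            "TRNT1L": {"pairs": {"truncation": {"alt_codon_index": 30,
                                                "alt_c": 88,
                                                "inter_start_c": [1, 88]}}},
            "NAXEL": {"pairs": {"truncation": {"alt_codon_index": 52,
                                               "alt_c": 154,
                                               "inter_start_c": [1, 154]}}},
        },
        "variants": [
            {"variant_id": "TRNT1L_c74ins20", "gene": "TRNT1L",
             "category": "annotated_only_LoF",
             "annotated_consequence": "frameshift",
             "annotated_p": "p.Gln25Hisfs*6",
             "alternative_consequence": "upstream_of_start"},
            {"variant_id": "TRNT1L_c88A_T", "gene": "TRNT1L",
             "category": "alternative_start_loss",
             "annotated_consequence": "missense", "annotated_p": "p.Met30Leu",
             "alternative_consequence": "start_loss"},
            {"variant_id": "TRNT1L_c88A_G", "gene": "TRNT1L",
             "category": "alternative_start_loss",
             "annotated_consequence": "missense", "annotated_p": "p.Met30Val",
             "alternative_consequence": "start_loss"},
            {"variant_id": "NAXEL_c128C_A", "gene": "NAXEL",
             "category": "annotated_only_LoF",
             "annotated_consequence": "nonsense", "annotated_p": "p.Ser43Ter",
             "alternative_consequence": "upstream_of_start"},
            {"variant_id": "NAXEL_c16C_T", "gene": "NAXEL",
             "category": "isoform_specific_missense",
             "annotated_consequence": "missense", "annotated_p": "p.Arg6Trp",
             "alternative_consequence": "upstream_of_start",
             "localization_change": True},
        ],
    }
    return SimBundle(genome, transcripts, tis_records, variants,
                     conservation_rows, truth)
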