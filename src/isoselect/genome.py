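"""Genome and transcript-annotation handling.

All coordinates are 0-based half-open internally.  File readers convert at the
boundary: GTF/GFF3 are 1-based inclusive, BED and bedGraph are 0-based
half-open, VCF is 1-based.  Coding-sequence ("c.") positions follow HGVS
numbering: c.1 is the A of the annotated start codon, upstream positions are
negative, and there is no c.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

_ALLOWED = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed or inconsistent genome/annotation input."""


class IntronicPositionError(ValueError):
    """A genomic position falls inside the transcript span but not in an exon."""


class OutOfTranscriptError(ValueError):
    """A genomic position falls outside the transcript span."""


class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    def __init__(self, contigs: dict[str, str]):
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - _ALLOWED
            if bad:
                raise AnnotationError(
                    f"contig {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            clean[name] = seq
        self._contigs = clean

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        contigs: dict[str, str] = {}
        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            n += 1
            if rec.id in contigs:
                raise AnnotationError(f"duplicate contig name {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq)
        if n == 0:
            raise AnnotationError(f"no FASTA records in {path}")
        return cls(contigs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def contigs(self) -> list[str]:
        return sorted(self._contigs)

    def length(self, contig: str) -> int:
        return len(self._get(contig))

    def _get(self, contig: str) -> str:
        try:
            return self._contigs[contig]
        except KeyError:
            raise AnnotationError(f"unknown contig {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of [start, end) on the forward strand; bounds-checked."""
        seq = self._get(contig)
        if not (0 <= start <= end <= len(seq)):
            raise AnnotationError(
                f"interval [{start}, {end}) outside contig {contig!r} (len {len(seq)})"
            )
        return seq[start:end]

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)


@dataclass(frozen=True)
class TranscriptCoordinate:
    """A position on a spliced transcript, with optional HGVS-style CDS position."""

    transcript_id: str
    position: int  # 0-based position in the spliced transcript
    cds_position: int | None = None  # c.-style; negative upstream, no zero


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure for one transcript.

    ``exons`` are genomic intervals in ascending genomic order regardless of
    strand.  ``cds_genomic`` is the genomic half-open span from the first base
    of the start codon through the last base of the stop codon.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_genomic: tuple[int, int] | None = None
    expression: float = 0.0
    pairing_excluded: str | None = None  # reason string when unusable for pairing

    _cum: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        self.exons = exons
        order = exons if self.strand == "+" else exons[::-1]
        cum = []
        total = 0
        for s, e in order:
            cum.append(total)
            total += e - s
        self._cum = tuple(cum)
        self._tx_order = order
        self._length = total
        if self.cds_genomic is not None:
            gs, ge = self.cds_genomic
            try:
                first = gs if self.strand == "+" else ge - 1
                last = ge - 1 if self.strand == "+" else gs
                t0 = self.genomic_to_tpos(first)
                t1 = self.genomic_to_tpos(last)
            except (IntronicPositionError, OutOfTranscriptError) as exc:
                raise AnnotationError(
                    f"{self.transcript_id}: CDS boundary outside exons"
                ) from exc
            self._cds_tstart = t0
            self._cds_tend = t1 + 1
            if self.cds_length % 3 != 0 and self.pairing_excluded is None:
                self.pairing_excluded = f"CDS length {self.cds_length} not divisible by 3"
        else:
            self._cds_tstart = None
            self._cds_tend = None

    # -- basic geometry ---------------------------------------------------

    @property
    def length(self) -> int:
        return self._length

    @property
    def is_coding(self) -> bool:
        return self.cds_genomic is not None

    @property
    def cds_tstart(self) -> int | None:
        """Transcript position of the first base of the annotated start codon."""
        return self._cds_tstart

    @property
    def cds_tend(self) -> int | None:
        """Transcript position one past the last base of the annotated stop codon."""
        return self._cds_tend

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        return self._cds_tend - self._cds_tstart

    @property
    def cds_start_genomic(self) -> int | None:
        """Genomic coordinate of the first base of the start codon (strand-aware)."""
        if self.cds_genomic is None:
            return None
        gs, ge = self.cds_genomic
        return gs if self.strand == "+" else ge - 1

    # -- coordinate conversion --------------------------------------------

    def genomic_to_tpos(self, gpos: int) -> int:
        span_lo, span_hi = self.exons[0][0], self.exons[-1][1]
        if not (span_lo <= gpos < span_hi):
            raise OutOfTranscriptError(
                f"{self.transcript_id}: genomic {gpos} outside transcript span"
            )
        for (s, e), off in zip(self._tx_order, self._cum):
            if s <= gpos < e:
                if self.strand == "+":
                    return off + (gpos - s)
                return off + (e - 1 - gpos)
        raise IntronicPositionError(f"{self.transcript_id}: genomic {gpos} is intronic")

    def tpos_to_genomic(self, tpos: int) -> int:
        if not (0 <= tpos < self._length):
            raise OutOfTranscriptError(
                f"{self.transcript_id}: transcript position {tpos} out of range"
            )
        for (s, e), off in zip(self._tx_order, self._cum):
            n = e - s
            if off <= tpos < off + n:
                if self.strand == "+":
                    return s + (tpos - off)
                return e - 1 - (tpos - off)
        raise AssertionError("unreachable")

    def c_position(self, tpos: int) -> int | None:
        """HGVS-style CDS position for a transcript position (None if non-coding)."""
        if self._cds_tstart is None:
            return None
        d = tpos - self._cds_tstart
        return d + 1 if d >= 0 else d

    def c_to_tpos(self, c: int) -> int:
        if self._cds_tstart is None:
            raise AnnotationError(f"{self.transcript_id}: non-coding transcript")
        if c == 0:
            raise ValueError("c.0 does not exist")
        return self._cds_tstart + (c - 1 if c > 0 else c)

    def genomic_to_transcript(self, gpos: int) -> TranscriptCoordinate:
        t = self.genomic_to_tpos(gpos)
        return TranscriptCoordinate(self.transcript_id, t, self.c_position(t))

    def transcript_to_genomic(self, coord: TranscriptCoordinate) -> int:
        return self.tpos_to_genomic(coord.position)

    # -- sequence ----------------------------------------------------------

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.fetch(self.contig, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def cds_sequence(self, genome: GenomeSequence) -> str:
        if not self.is_coding:
            return ""
        return self.spliced_sequence(genome)[self._cds_tstart : self._cds_tend]

    def project_to_genomic(self, t_lo: int, t_hi: int) -> list[tuple[int, int]]:
        """Genomic intervals (ascending) covered by transcript range [t_lo, t_hi)."""
        g = sorted(self.tpos_to_genomic(t) for t in range(t_lo, t_hi))
        out: list[tuple[int, int]] = []
        for pos in g:
            if out and out[-1][1] == pos:
                out[-1] = (out[-1][0], pos + 1)
            else:
                out.append((pos, pos + 1))
        return out


def gtf_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """GTF/GFF 1-based inclusive interval -> internal 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_gtf(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


def _normalize_chrom(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


def load_genome(path) -> GenomeSequence:
    """Read a genome FASTA into memory (bases uppercased, alphabet-checked)."""
    return GenomeSequence.from_fasta(path)


def load_annotation(
    path,
    genome: GenomeSequence,
    *,
    validate_start: bool = True,
    chrom_normalize: bool = False,
) -> dict[str, TranscriptModel]:
    """Read transcript models from GTF or GFF3.

    Transcripts lacking CDS features are retained but non-coding.  Transcripts
    whose CDS length is not a multiple of 3, or (when ``validate_start`` is on)
    whose annotated start codon is not ATG, are flagged ``pairing_excluded``
    rather than dropped.  GENCODE-style separate ``stop_codon`` features are
    folded into the CDS span.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )

    # Map transcript id -> gene id from transcript/mRNA parents (GFF3) as a
    # fallback when exon lines carry no gene_id attribute (GTF always does).
    tid_gene: dict[str, str] = {}
    tid_expr: dict[str, float] = {}
    for ftype in ("transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            tid = f.attributes.get("transcript_id", [f.id])[0]
            gene = f.attributes.get("gene_id", f.attributes.get("Parent", [tid]))[0]
            tid_gene[tid] = gene
            if "expression" in f.attributes:
                tid_expr[tid] = float(f.attributes["expression"][0])

    def ids_of(f) -> tuple[str, str]:
        if "transcript_id" in f.attributes:
            tid = f.attributes["transcript_id"][0]
        elif "Parent" in f.attributes:
            tid = f.attributes["Parent"][0]
        else:
            raise AnnotationError(f"feature without transcript attribution: {f}")
        gene = f.attributes.get("gene_id", [tid_gene.get(tid, tid)])[0]
        return tid, gene

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid, gene = ids_of(f)
        contig = _normalize_chrom(f.seqid) if chrom_normalize else f.seqid
        meta.setdefault(tid, (gene, contig, f.strand))
        iv = gtf_to_internal(f.start, f.end)
        if f.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)
        if "expression" in f.attributes and tid not in tid_expr:
            tid_expr[tid] = float(f.attributes["expression"][0])

    models: dict[str, TranscriptModel] = {}
    for tid, (gene, contig, strand) in meta.items():
        if contig not in genome:
            raise AnnotationError(f"{tid}: unknown contig {contig!r}")
        ex = sorted(exons.get(tid, []))
        if not ex:
            log.warning("transcript %s has no exon features; skipped", tid)
            continue
        cds_span = None
        if tid in cds:
            blocks = sorted(cds[tid])
            lo, hi = blocks[0][0], blocks[-1][1]
            for s, e in blocks:
                if not any(xs <= s and e <= xe for xs, xe in ex):
                    raise AnnotationError(f"{tid}: CDS block [{s},{e}) outside exons")
            cds_span = (lo, hi)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene,
            contig=contig,
            strand=strand,
            exons=tuple(ex),
            cds_genomic=cds_span,
            expression=tid_expr.get(tid, 0.0),
        )
        if model.is_coding and model.pairing_excluded is None and validate_start:
            start = model.cds_sequence(genome)[:3]
            if start != "ATG":
                model.pairing_excluded = f"annotated start codon {start} is not ATG"
        if model.pairing_excluded:
            log.info("transcript %s excluded from pairing: %s", tid, model.pairing_excluded)
        models[tid] = model
    return models
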