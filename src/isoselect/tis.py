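"""Translation-initiation-site catalog and isoform-pair assembly.

Empirically called initiation sites (e.g. from harringtonine ribosome
profiling) are classified by ORF type relative to the annotated CDS of each
transcript, the strongest site per ORF type per gene is selected by
initiation efficiency (footprint reads / mRNA abundance), and
annotated/alternative proteoform pairs are assembled.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .genome import (
    STOP_CODONS,
    GenomeSequence,
    IntronicPositionError,
    OutOfTranscriptError,
    TranscriptModel,
)

log = logging.getLogger(__name__)

ORF_TYPES = ("annotated", "extension", "truncation", "uORF", "other")

NEAR_COGNATE = frozenset(
    {"CTG", "GTG", "TTG", "ACG", "ATC", "ATA", "ATT", "AGG", "AAG"}
)


class TISError(ValueError):
    pass


@dataclass
class TISRecord:
    """One called translation initiation site.

    The codon interval is genomic, 0-based half-open, exactly 3 nt, and must
    be fully exonic on the assigned transcript.  ``codon`` is the DNA codon on
    the transcript strand (AUG written ATG).
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    codon_start: int
    codon_end: int
    codon: str
    footprint_reads: float
    mrna_abundance: float
    orf_type: str | None = None
    tpos: int | None = None  # transcript position of the codon's first base
    excluded: bool = False  # e.g. ambiguous uORF/extension sites
    note: str = ""

    def __post_init__(self):
        if self.codon_end - self.codon_start != 3:
            raise TISError(
                f"{self.gene_id}: start-codon interval must be exactly 3 nt "
                f"(got [{self.codon_start}, {self.codon_end}))"
            )
        self.codon = self.codon.upper().replace("U", "T")
        if self.footprint_reads < 0:
            raise TISError("negative footprint read count")

    @property
    def efficiency(self) -> float:
        return compute_efficiency(self.footprint_reads, self.mrna_abundance)


def compute_efficiency(footprint_reads: float, mrna_abundance: float) -> float:
    """Translation initiation efficiency: footprint reads normalised to mRNA abundance."""
    if mrna_abundance <= 0:
        raise TISError(f"mRNA abundance must be positive (got {mrna_abundance})")
    if footprint_reads < 0:
        raise TISError(f"negative footprint reads ({footprint_reads})")
    return footprint_reads / mrna_abundance


def read_tis_table(path) -> list[TISRecord]:
    """Read a BED6+3 TIS table.

    Columns: chrom, start, end (codon interval, BED half-open), name as
    ``gene|transcript``, score (unused), strand, codon, footprint_reads,
    mrna_abundance.
    """
    out: list[TISRecord] = []
    with open(path) as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith(("#", "track")):
                continue
            if len(row) < 9:
                raise TISError(f"{path}:{ln}: expected 9 tab-separated columns")
            gene, _, tid = row[3].partition("|")
            out.append(
                TISRecord(
                    gene_id=gene,
                    transcript_id=tid,
                    contig=row[0],
                    strand=row[5],
                    codon_start=int(row[1]),
                    codon_end=int(row[2]),
                    codon=row[6],
                    footprint_reads=float(row[7]),
                    mrna_abundance=float(row[8]),
                )
            )
    return out


def write_tis_table(records: list[TISRecord], path) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in records:
            w.writerow(
                [
                    r.contig,
                    r.codon_start,
                    r.codon_end,
                    f"{r.gene_id}|{r.transcript_id}",
                    0,
                    r.strand,
                    r.codon,
                    r.footprint_reads,
                    r.mrna_abundance,
                ]
            )


# ---------------------------------------------------------------------------
# ORF-type classification


def tis_tpos(tis: TISRecord, t: TranscriptModel) -> int:
    """Transcript position of the codon's first base; requires the 3 bases to
    be exonic and contiguous in transcript space (junction-spanning start
    codons are not supported)."""
    gfirst = tis.codon_start if t.strand == "+" else tis.codon_end - 1
    try:
        tp = [t.genomic_to_tpos(g) for g in range(tis.codon_start, tis.codon_end)]
    except (IntronicPositionError, OutOfTranscriptError) as exc:
        raise TISError(
            f"TIS {tis.gene_id}@{tis.codon_start} not exonic on {t.transcript_id}"
        ) from exc
    t0 = t.genomic_to_tpos(gfirst)
    if sorted(tp) != [t0, t0 + 1, t0 + 2]:
        raise TISError(
            f"TIS {tis.gene_id}@{tis.codon_start} spans a splice junction on "
            f"{t.transcript_id}"
        )
    return t0


def classify_orf_type(
    tis: TISRecord, t: TranscriptModel, genome: GenomeSequence
) -> str:
    """ORF type of a TIS relative to the annotated CDS of transcript ``t``.

    annotated   — at the annotated start codon;
    truncation  — downstream, in frame, before the annotated stop (shares it);
    extension   — upstream, in frame, no in-frame stop before the annotated start;
    uORF        — upstream and out of frame, or upstream in frame but with an
                  in-frame stop before the annotated start;
    other       — anything else (e.g. downstream out-of-frame).
    """
    if not t.is_coding:
        raise TISError(f"transcript {t.transcript_id} has no CDS")
    t0 = tis_tpos(tis, t)
    cs, ce = t.cds_tstart, t.cds_tend
    if t0 == cs:
        return "annotated"
    if t0 > cs:
        if (t0 - cs) % 3 == 0 and t0 < ce - 3:
            return "truncation"
        return "other"
    # upstream
    if (cs - t0) % 3 != 0:
        return "uORF"
    seq = t.spliced_sequence(genome)
    for i in range(t0, cs, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return "uORF"
    return "extension"


def resolve_uorf_extension_ambiguity(
    tis: TISRecord,
    transcripts: list[TranscriptModel],
    genome: GenomeSequence,
) -> tuple[str, bool]:
    """Final ORF type of one genomic TIS across all transcripts of its gene.

    A site called a uORF on any transcript but an extension on another is
    finalised as a uORF and excluded from extension pairing, so only
    unambiguous N-terminal extensions enter pairs.  Returns
    ``(orf_type, excluded)``.
    """
    types: set[str] = set()
    for t in transcripts:
        if not t.is_coding or t.pairing_excluded:
            continue
        try:
            types.add(classify_orf_type(tis, t, genome))
        except TISError:
            continue  # not exonic / junction-spanning on this transcript
    if not types:
        raise TISError(
            f"TIS {tis.gene_id}@{tis.codon_start} not classifiable on any transcript"
        )
    if "uORF" in types and "extension" in types:
        return "uORF", True
    for preferred in ("annotated", "truncation", "extension", "uORF", "other"):
        if preferred in types:
            return preferred, False
    raise AssertionError("unreachable")


def select_strongest(records: list[TISRecord]) -> dict[str, TISRecord]:
    """Strongest TIS per ORF type for one gene's catalog.

    Maximal initiation efficiency wins; exact ties go to the more 5' site in
    transcript coordinates, then to the lexicographically smallest
    transcript id.  Excluded (ambiguous) records are skipped.
    """
    best: dict[str, TISRecord] = {}
    for r in records:
        if r.orf_type is None:
            raise TISError("select_strongest requires classified records")
        if r.excluded:
            continue
        cur = best.get(r.orf_type)
        if cur is None:
            best[r.orf_type] = r
            continue
        key_new = (-r.efficiency, r.tpos if r.tpos is not None else 0, r.transcript_id)
        key_cur = (
            -cur.efficiency,
            cur.tpos if cur.tpos is not None else 0,
            cur.transcript_id,
        )
        if key_new < key_cur:
            best[r.orf_type] = r
    return best


# ---------------------------------------------------------------------------
# Pair assembly


@dataclass
class IsoformPair:
    """An (annotated, alternative) N-terminal proteoform pair.

    For truncation pairs the alternative start is downstream of and in frame
    with the annotated start and shares its stop codon; for extension pairs it
    is upstream, in frame, with no in-frame stop before the annotated start.
    ``alt_c`` is the c.-position of the alternative start codon's first base
    (truncation: 3*(k-1)+1 for alt start at codon k; extension: negative).
    """

    gene_id: str
    transcript_id: str
    pair_type: str  # "truncation" | "extension"
    alternative: TISRecord
    alt_tpos: int
    alt_c: int
    annotated_efficiency: float | None = None

    @property
    def alt_codon_index(self) -> int | None:
        """1-based codon index of a truncation's alternative start (None for extensions)."""
        if self.pair_type != "truncation":
            return None
        return (self.alt_c - 1) // 3 + 1

    @property
    def extension_codons(self) -> int | None:
        """Number of extra N-terminal codons of an extension (None for truncations)."""
        if self.pair_type != "extension":
            return None
        return (-self.alt_c) // 3

    def inter_start_c(self) -> tuple[int, int]:
        """c.-interval strictly between the two start codons (half-open).

        Truncation: [c.1, alt_c); extension: [alt_c, c.1)."""
        if self.pair_type == "truncation":
            return (1, self.alt_c)
        return (self.alt_c, 1)

    def inter_start_genomic(self, t: TranscriptModel) -> list[tuple[int, int]]:
        lo_c, hi_c = self.inter_start_c()
        t_lo = t.c_to_tpos(lo_c)
        t_hi = t.c_to_tpos(hi_c)
        return t.project_to_genomic(t_lo, t_hi)


def classify_catalog(
    records: list[TISRecord],
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
) -> list[TISRecord]:
    """Classify every TIS on its assigned transcript, then resolve the
    uORF-vs-extension ambiguity across each gene's transcripts."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)
    out: list[TISRecord] = []
    for r in records:
        t = transcripts.get(r.transcript_id)
        if t is None:
            log.warning("TIS %s: unknown transcript %s; skipped", r.gene_id, r.transcript_id)
            continue
        if not t.is_coding or t.pairing_excluded:
            log.info(
                "TIS %s@%d on unusable transcript %s; skipped",
                r.gene_id, r.codon_start, r.transcript_id,
            )
            continue
        r.tpos = tis_tpos(r, t)
        own = classify_orf_type(r, t, genome)
        final, excl = resolve_uorf_extension_ambiguity(
            r, by_gene.get(r.gene_id, [t]), genome
        )
        if own in ("annotated", "truncation"):
            # downstream classes are transcript-local; ambiguity resolution
            # only governs upstream uORF/extension sites
            final, excl = own, False
        r.orf_type = final
        r.excluded = excl
        if excl:
            r.note = "ambiguous uORF/extension; excluded from pairing"
        out.append(r)
    return out


def build_isoform_pairs(
    records: list[TISRecord],
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
) -> list[IsoformPair]:
    """Assemble at most one truncation and one extension pair per gene.

    ``records`` must already be classified.  Sequence generation uses the
    most highly expressed transcript on which the alternative TIS is usable
    (ties to the smallest transcript id).
    """
    by_gene: dict[str, list[TISRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        tx_by_gene.setdefault(t.gene_id, []).append(t)

    pairs: list[IsoformPair] = []
    for gene in sorted(by_gene):
        best = select_strongest(by_gene[gene])
        ann_eff = best["annotated"].efficiency if "annotated" in best else None
        for pair_type in ("truncation", "extension"):
            alt = best.get(pair_type)
            if alt is None:
                continue
            candidates = []
            for t in tx_by_gene.get(gene, []):
                if not t.is_coding or t.pairing_excluded:
                    continue
                try:
                    t0 = tis_tpos(alt, t)
                except TISError:
                    continue
                if classify_orf_type(alt, t, genome) == pair_type:
                    candidates.append((t, t0))
            if not candidates:
                log.warning(
                    "gene %s: %s TIS violates pair invariants on all transcripts; "
                    "pair dropped", gene, pair_type,
                )
                continue
            candidates.sort(key=lambda ct: (-ct[0].expression, ct[0].transcript_id))
            t, t0 = candidates[0]
            pairs.append(
                IsoformPair(
                    gene_id=gene,
                    transcript_id=t.transcript_id,
                    pair_type=pair_type,
                    alternative=alt,
                    alt_tpos=t0,
                    alt_c=t.c_position(t0),
                    annotated_efficiency=ann_eff,
                )
            )
    return pairs


def write_pair_table(
    pairs: list[IsoformPair], transcripts: dict[str, TranscriptModel], path
) -> None:
    """TSV pair table: gene, pair type, inter-start c.-interval, codons, efficiencies."""
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "gene_id",
                "transcript_id",
                "pair_type",
                "alt_start_c",
                "inter_start_c_lo",
                "inter_start_c_hi",
                "alt_codon",
                "alt_efficiency",
                "annotated_efficiency",
            ]
        )
        for p in sorted(pairs, key=lambda p: (p.gene_id, p.pair_type)):
            lo, hi = p.inter_start_c()
            w.writerow(
                [
                    p.gene_id,
                    p.transcript_id,
                    p.pair_type,
                    p.alt_c,
                    lo,
                    hi,
                    p.alternative.codon,
                    f"{p.alternative.efficiency:.6g}",
                    "" if p.annotated_efficiency is None
                    else f"{p.annotated_efficiency:.6g}",
                ]
            )
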