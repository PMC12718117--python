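"""Proteoform sequence generation for isoform pairs.

Amino-acid sequences are produced for the annotated and alternative isoform
of each pair by translating the spliced transcript from the respective start
codon with the standard genetic code.  Near-cognate start codons (CUG, GUG,
...) translate with initiator Met, as initiator-tRNA delivers Met regardless
of codon identity.  Stop-codon readthrough, selenocysteine and organellar
codes are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSequence, TranscriptModel
from .tis import IsoformPair

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = frozenset(standard_dna_table.stop_codons)

#: FLAG-S masking tag appended N-terminally to test signal internalisation.
FLAG_S_TAG = "MDYKDDDDKGKETAAAKFERQHMDSGGT"

#: Tandem SV40 nuclear localization signal (synthetic 2xNLS stand-in).
NLS_2X_TAG = "MPKKKRKVPKKKRKV"


class ProteoformError(ValueError):
    pass


def translate_cds(nt: str, initiator: bool = True) -> tuple[str, bool]:
    """Translate a nucleotide string, stopping at the first stop codon.

    Returns ``(protein, runs_off)`` where ``runs_off`` flags a sequence that
    ended (or left a partial codon) before any stop codon.  With ``initiator``
    the first codon is rendered M regardless of identity.
    """
    nt = nt.upper().replace("U", "T")
    if len(nt) < 3:
        raise ProteoformError(f"sequence shorter than one codon ({len(nt)} nt)")
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in _STOPS:
            return "".join(aa), False
        if i == 0 and initiator:
            aa.append("M")
        else:
            try:
                aa.append(_CODON_TABLE[codon])
            except KeyError:
                aa.append("X")  # ambiguous (N-containing) codon
    return "".join(aa), True


@dataclass
class Proteoform:
    """One protein product of a gene, distinguished by its start codon."""

    proteoform_id: str  # gene|pair_type|role
    gene_id: str
    pair_type: str
    role: str  # "annotated" | "alternative"
    sequence: str
    start_codon: str
    transcript_id: str
    c_start: int
    cds_genomic: list[tuple[int, int]]
    runs_off: bool = False

    def __post_init__(self):
        if not self.sequence or self.sequence[0] != "M":
            raise ProteoformError(
                f"{self.proteoform_id}: proteoform must start with M"
            )
        if "*" in self.sequence:
            raise ProteoformError(f"{self.proteoform_id}: internal stop symbol")

    def __len__(self) -> int:
        return len(self.sequence)


def build_proteoform(
    pair: IsoformPair,
    role: str,
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
) -> Proteoform:
    """Translate one isoform of a pair on its designated transcript."""
    if role not in ("annotated", "alternative"):
        raise ProteoformError(f"unknown role {role!r}")
    t = transcripts[pair.transcript_id]
    seq = t.spliced_sequence(genome)
    if role == "annotated":
        start_tpos = t.cds_tstart
        start_codon = seq[start_tpos : start_tpos + 3]
        c_start = 1
    else:
        start_tpos = pair.alt_tpos
        start_codon = pair.alternative.codon
        c_start = pair.alt_c
    protein, runs_off = translate_cds(seq[start_tpos:], initiator=True)
    t_end = start_tpos + 3 * len(protein) + (0 if runs_off else 3)
    return Proteoform(
        proteoform_id=f"{pair.gene_id}|{pair.pair_type}|{role}",
        gene_id=pair.gene_id,
        pair_type=pair.pair_type,
        role=role,
        sequence=protein,
        start_codon=start_codon,
        transcript_id=t.transcript_id,
        c_start=c_start,
        cds_genomic=t.project_to_genomic(start_tpos, t_end),
        runs_off=runs_off,
    )


def build_pair_proteoforms(
    pair: IsoformPair,
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
) -> tuple[Proteoform, Proteoform]:
    return (
        build_proteoform(pair, "annotated", transcripts, genome),
        build_proteoform(pair, "alternative", transcripts, genome),
    )


def signal_region(pair: IsoformPair, proteoform: Proteoform) -> str:
    """Candidate localization-signal region differing between the isoforms.

    Truncation pair: residues 1 .. (alternative-start residue - 1) of the
    annotated proteoform (e.g. Met1-Val51 for an alternative start at Met52).
    Extension pair: the extension residues alone (from the extended, i.e.
    alternative, proteoform).
    """
    if pair.pair_type == "truncation":
        if proteoform.role != "annotated":
            raise ProteoformError(
                "truncation signal region is taken from the annotated proteoform"
            )
        return proteoform.sequence[: pair.alt_codon_index - 1]
    if proteoform.role != "alternative":
        raise ProteoformError(
            "extension signal region is taken from the extended proteoform"
        )
    return proteoform.sequence[: pair.extension_codons]


def prepend_tag(p: Proteoform, tag: str) -> str:
    """N-terminal masking construct: tag followed by the full native sequence."""
    if not tag:
        raise ProteoformError("tag must be non-empty")
    return tag + p.sequence


def write_proteoform_fasta(proteoforms: list[Proteoform], path) -> None:
    """Write proteoforms as FASTA, sorted by (gene, pair_type, role).

    Header grammar: ``gene|pair_type|role start_codon=XXX c_start=N
    transcript=TID`` — stable IDs let external predictor output be joined
    back by proteoform_id.
    """
    ids = [p.proteoform_id for p in proteoforms]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ProteoformError(f"duplicate proteoform ids: {sorted(dupes)}")
    recs = [
        SeqRecord(
            Seq(p.sequence),
            id=p.proteoform_id,
            description=(
                f"start_codon={p.start_codon} c_start={p.c_start} "
                f"transcript={p.transcript_id}"
            ),
        )
        for p in sorted(proteoforms, key=lambda p: (p.gene_id, p.pair_type, p.role))
    ]
    seqio_write(recs, str(path), "fasta")
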