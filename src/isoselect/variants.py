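"""Variant parsing, per-isoform consequence calling, and isoform-selective
allele (ISA) classification.

A variant is evaluated once per isoform of a pair by mutating the spliced
transcript, translating from the (position-mapped) start codon of that
isoform, and comparing the mutant protein to wild type.  A nonsense or
frameshift confined to the region between the two start codons eliminates
only the longer isoform; a variant overlapping the alternative start codon
abolishes the alternative isoform while reading as an innocuous missense
change on the annotated one.

Indels are normalised to a left-aligned minimal representation (shared
prefixes/suffixes trimmed, no HGVS 3'-rule shifting).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio.SeqUtils import seq3
from intervaltree import IntervalTree

from .genome import (
    GenomeSequence,
    IntronicPositionError,
    OutOfTranscriptError,
    TranscriptModel,
    reverse_complement,
)
from .proteoform import translate_cds
from .tis import IsoformPair

log = logging.getLogger(__name__)

CONSEQUENCES = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "start_loss",
    "stop_loss",
    "upstream_of_start",
    "non_coding",
)

ISA_CATEGORIES = (
    "annotated_only_LoF",
    "alternative_only_LoF",  # extension-pair generalisation of the above
    "alternative_start_loss",
    "isoform_specific_missense",
    "shared",
    "outside_pair_scope",
)

LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift"})
_PROTEIN_AFFECTING = frozenset(
    {"missense", "nonsense", "frameshift", "start_loss", "stop_loss"}
)


class VariantError(ValueError):
    pass


class UnsupportedVariantError(VariantError):
    """Variant spans an exon/intron boundary on the transcript in question."""


@dataclass
class VariantRecord:
    """One normalised variant (forward-strand genomic alleles)."""

    contig: str
    pos: int  # original 1-based position
    ref: str
    alt: str
    significance: str = ""
    condition: str = ""
    variant_id: str = ""
    # normalised minimal representation (0-based; nref or nalt may be empty)
    pos0: int = field(init=False)
    nref: str = field(init=False)
    nalt: str = field(init=False)

    def __post_init__(self):
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.ref or not self.alt:
            raise VariantError(f"{self}: empty allele")
        p0, r, a = self.pos - 1, self.ref, self.alt
        while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            r, a = r[1:], a[1:]
            p0 += 1
        if len(r) != len(a) and r and a and r[0] == a[0]:
            r, a = r[1:], a[1:]
            p0 += 1
        self.pos0, self.nref, self.nalt = p0, r, a

    @property
    def variant_class(self) -> str:
        if len(self.nref) == 1 and len(self.nalt) == 1:
            return "SNV"
        if not self.nref:
            return "insertion"
        if not self.nalt:
            return "deletion"
        return "delins"

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic footprint (half-open): ref span; for a pure insertion, the
        single base after which insertion occurs."""
        if self.nref:
            return (self.pos0, self.pos0 + len(self.nref))
        return (self.pos0 - 1, self.pos0)

    def key(self) -> tuple:
        return (self.contig, self.pos0, self.nref, self.nalt)

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"


_DEFAULT_TSV_COLUMNS = {
    "contig": "Chromosome",
    "pos": "Position",
    "ref": "ReferenceAllele",
    "alt": "AlternateAllele",
    "significance": "ClinicalSignificance",
    "condition": "Condition",
}


def parse_variants(
    path,
    genome: GenomeSequence,
    *,
    columns: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read variants from VCF (multi-allelic rows split) or a ClinVar-style
    TSV, validating reference alleles against the genome.  Records failing
    validation are rejected with a log message."""
    path = str(path)
    raw: list[VariantRecord] = []
    if path.endswith((".vcf", ".vcf.gz")):
        try:
            vf = pysam.VariantFile(path)
        except (OSError, ValueError) as exc:
            raise VariantError(f"malformed VCF {path}: {exc}") from exc
        with vf:
            for rec in vf:
                for alt in rec.alts or ():
                    if alt.startswith("<") or alt == "*":
                        log.warning("%s:%d symbolic allele %s skipped", rec.chrom, rec.pos, alt)
                        continue
                    try:
                        sig = str(rec.info.get("CLNSIG", "") or "")
                    except (KeyError, ValueError):
                        sig = ""
                    raw.append(
                        VariantRecord(
                            contig=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            variant_id=rec.id or "",
                            significance=sig,
                        )
                    )
    else:
        colmap = dict(_DEFAULT_TSV_COLUMNS, **(columns or {}))
        df = pd.read_csv(path, sep="\t", dtype=str)
        for need in ("contig", "pos", "ref", "alt"):
            if colmap[need] not in df.columns:
                raise VariantError(f"{path}: missing column {colmap[need]!r}")
        for row in df.itertuples(index=False):
            d = row._asdict() if hasattr(row, "_asdict") else dict(row)
            try:
                pos = int(d[colmap["pos"]])
            except (TypeError, ValueError) as exc:
                raise VariantError(f"{path}: malformed position {d[colmap['pos']]!r}") from exc
            for alt in str(d[colmap["alt"]]).split(","):
                raw.append(
                    VariantRecord(
                        contig=str(d[colmap["contig"]]),
                        pos=pos,
                        ref=str(d[colmap["ref"]]),
                        alt=alt.strip(),
                        significance=str(d.get(colmap["significance"], "") or ""),
                        condition=str(d.get(colmap["condition"], "") or ""),
                    )
                )
    out: list[VariantRecord] = []
    for v in raw:
        if v.contig not in genome:
            log.warning("%s: unknown contig; rejected", v)
            continue
        observed = genome.fetch(v.contig, v.pos - 1, v.pos - 1 + len(v.ref))
        if observed != v.ref:
            log.warning("%s: reference mismatch (genome has %s); rejected", v, observed)
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Applying a variant to a spliced transcript


@dataclass
class AppliedVariant:
    """A variant projected into transcript space.

    ``t_lo``/``t_hi`` delimit the replaced transcript interval (equal for a
    pure insertion) and ``alt_seq`` is the transcript-strand replacement.
    ``posmap[i]`` carries wild-type transcript position i to its mutated
    coordinate (None for deleted bases).
    """

    applicable: bool
    sequence: str
    t_lo: int = 0
    t_hi: int = 0
    alt_seq: str = ""
    posmap: list[int | None] = field(default_factory=list)

    @property
    def delta(self) -> int:
        return len(self.alt_seq) - (self.t_hi - self.t_lo)


def apply_variant(
    t: TranscriptModel, genome: GenomeSequence, v: VariantRecord
) -> AppliedVariant:
    """Mutated spliced sequence of ``t`` plus the wild-type->mutant position map.

    Intronic variants leave the spliced sequence unchanged (``applicable`` is
    False); variants spanning an exon/intron boundary raise
    :class:`UnsupportedVariantError`.
    """
    if v.contig != t.contig:
        return AppliedVariant(False, t.spliced_sequence(genome))
    seq = t.spliced_sequence(genome)

    def tpos_or_none(g: int) -> int | None:
        try:
            return t.genomic_to_tpos(g)
        except (IntronicPositionError, OutOfTranscriptError):
            return None

    if v.nref:
        tps = [tpos_or_none(g) for g in range(v.pos0, v.pos0 + len(v.nref))]
        if all(p is None for p in tps):
            return AppliedVariant(False, seq)
        if any(p is None for p in tps):
            raise UnsupportedVariantError(f"{v}: spans an exon boundary on {t.transcript_id}")
        lo, hi = min(tps), max(tps) + 1
        if hi - lo != len(v.nref):
            raise UnsupportedVariantError(f"{v}: spans a splice junction on {t.transcript_id}")
        alt_t = v.nalt if t.strand == "+" else reverse_complement(v.nalt)
        t_lo, t_hi = lo, hi
    else:  # pure insertion between pos0-1 and pos0
        left, right = tpos_or_none(v.pos0 - 1), tpos_or_none(v.pos0)
        if left is None and right is None:
            return AppliedVariant(False, seq)
        if left is None or right is None or abs(left - right) != 1:
            raise UnsupportedVariantError(
                f"{v}: insertion at an exon boundary on {t.transcript_id}"
            )
        t_lo = t_hi = right if t.strand == "+" else min(left, right) + 1
        alt_t = v.nalt if t.strand == "+" else reverse_complement(v.nalt)

    mut = seq[:t_lo] + alt_t + seq[t_hi:]
    shift = len(alt_t) - (t_hi - t_lo)
    posmap: list[int | None] = []
    for i in range(len(seq)):
        if i < t_lo:
            posmap.append(i)
        elif i < t_hi:
            # same-length substitutions preserve positions; unbalanced edits
            # leave replaced bases without a mutant coordinate
            posmap.append(i if shift == 0 else None)
        else:
            posmap.append(i + shift)
    return AppliedVariant(True, mut, t_lo, t_hi, alt_t, posmap)


# ---------------------------------------------------------------------------
# Consequence calling


@dataclass
class ConsequenceCall:
    role: str
    consequence: str
    c_notation: str
    p_notation: str
    mutant_protein: str | None = None
    first_changed_residue: int | None = None  # 1-based in the role's protein


def _c_str(t: TranscriptModel, tpos: int) -> str:
    c = t.c_position(tpos)
    return str(c) if c is not None else "?"


def c_notation(t: TranscriptModel, app: AppliedVariant, seq: str) -> str:
    """HGVS-style c. description relative to the annotated start of ``t``."""
    if not app.applicable:
        return "c.?"
    lo, hi, alt = app.t_lo, app.t_hi, app.alt_seq
    if hi - lo == 1 and len(alt) == 1:
        return f"c.{_c_str(t, lo)}{seq[lo]}>{alt}"
    if not alt:
        if hi - lo == 1:
            return f"c.{_c_str(t, lo)}del"
        return f"c.{_c_str(t, lo)}_{_c_str(t, hi - 1)}del"
    if lo == hi:
        return f"c.{_c_str(t, lo - 1)}_{_c_str(t, lo)}ins{alt}"
    if hi - lo == 1:
        return f"c.{_c_str(t, lo)}delins{alt}"
    return f"c.{_c_str(t, lo)}_{_c_str(t, hi - 1)}delins{alt}"


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def consequence_for_isoform(
    v: VariantRecord,
    pair: IsoformPair,
    role: str,
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
) -> ConsequenceCall:
    """Per-isoform consequence: translate the mutated spliced sequence from the
    role's position-mapped start codon and compare to wild type."""
    t = transcripts[pair.transcript_id]
    seq = t.spliced_sequence(genome)
    app = apply_variant(t, genome, v)
    cnote = c_notation(t, app, seq)
    if not app.applicable:
        return ConsequenceCall(role, "non_coding", cnote, "p.?")

    s = t.cds_tstart if role == "annotated" else pair.alt_tpos
    wt_codon = seq[s : s + 3]
    s_mut = app.posmap[s]
    if s_mut is None or app.sequence[s_mut : s_mut + 3] != wt_codon:
        return ConsequenceCall(role, "start_loss", cnote, "p.Met1?", mutant_protein=None,
                               first_changed_residue=1)

    wt_prot, _ = translate_cds(seq[s:], initiator=True)
    mut_prot, mut_runs = translate_cds(app.sequence[s_mut:], initiator=True)

    if mut_prot == wt_prot:
        if app.t_hi <= s:
            cons = "upstream_of_start"
        elif app.t_lo >= s + 3 * len(wt_prot) + 3:
            cons = "non_coding"  # exonic but 3' of the stop codon
        else:
            cons = "synonymous"
        p = "p.(=)"
        if cons == "synonymous" and app.t_hi - app.t_lo == 1:
            i = (app.t_lo - s) // 3
            if i < len(wt_prot):
                p = f"p.{_aa3(wt_prot[i])}{i + 1}="
        return ConsequenceCall(role, cons, cnote, p, mutant_protein=mut_prot)

    # first differing residue (0-based)
    i = next(
        (k for k in range(min(len(wt_prot), len(mut_prot))) if wt_prot[k] != mut_prot[k]),
        min(len(wt_prot), len(mut_prot)),
    )

    if app.delta % 3 != 0:
        wt_res = _aa3(wt_prot[i]) if i < len(wt_prot) else "Ter"
        if i >= len(mut_prot):  # shifted frame hits a stop at the first changed codon
            p = f"p.{wt_res}{i + 1}Ter"
        else:
            n = "?" if mut_runs else str(len(mut_prot) - i + 1)
            p = f"p.{wt_res}{i + 1}{_aa3(mut_prot[i])}fs*{n}"
        return ConsequenceCall(role, "frameshift", cnote, p, mut_prot, i + 1)

    if len(mut_prot) < len(wt_prot) and wt_prot.startswith(mut_prot):
        k = len(mut_prot)
        return ConsequenceCall(
            role, "nonsense", cnote, f"p.{_aa3(wt_prot[k])}{k + 1}Ter", mut_prot, k + 1
        )
    if len(mut_prot) > len(wt_prot) and mut_prot.startswith(wt_prot):
        k = len(wt_prot)
        ext = len(mut_prot) - len(wt_prot)
        return ConsequenceCall(
            role, "stop_loss", cnote,
            f"p.Ter{k + 1}{_aa3(mut_prot[k])}ext*{ext}", mut_prot, k + 1,
        )
    if len(mut_prot) == len(wt_prot):
        diffs = [k for k in range(len(wt_prot)) if wt_prot[k] != mut_prot[k]]
        if len(diffs) == 1:
            k = diffs[0]
            p = f"p.{_aa3(wt_prot[k])}{k + 1}{_aa3(mut_prot[k])}"
        else:
            k, k2 = diffs[0], diffs[-1]
            p = (
                f"p.{_aa3(wt_prot[k])}{k + 1}_{_aa3(wt_prot[k2])}{k2 + 1}"
                f"delins{''.join(_aa3(a) for a in mut_prot[k : k2 + 1])}"
            )
        return ConsequenceCall(role, "missense", cnote, p, mut_prot, diffs[0] + 1)
    # in-frame indel altering the protein: reported as a (non-truncating)
    # missense-class change; stop-gaining in-frame indels surface as nonsense
    if len(mut_prot) < len(wt_prot) and not mut_runs and i >= len(mut_prot):
        return ConsequenceCall(
            role, "nonsense", cnote, f"p.{_aa3(wt_prot[i])}{i + 1}Ter", mut_prot, i + 1
        )
    p = f"p.{_aa3(wt_prot[i])}{i + 1}delins"
    return ConsequenceCall(role, "missense", cnote, p, mut_prot, i + 1)


# ---------------------------------------------------------------------------
# ISA classification


@dataclass
class ISACall:
    variant: VariantRecord
    gene_id: str
    pair_type: str
    category: str
    consequences: dict[str, ConsequenceCall]
    kozak_flag: bool = False
    near_cognate_alt: bool = False
    extension_generalized: bool = False


def classify_isa(
    v: VariantRecord,
    pair: IsoformPair,
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
    *,
    near_cognate_start_loss: bool = False,
) -> ISACall:
    """Classify a variant against one isoform pair.

    Categories: ``annotated_only_LoF`` (nonsense/frameshift strictly between
    the starts of a truncation pair, sparing the truncated isoform),
    ``alternative_only_LoF`` (the analogous call on extension pairs),
    ``alternative_start_loss`` (variant changes the alternative start codon;
    AUG starts only unless ``near_cognate_start_loss``),
    ``isoform_specific_missense``, ``shared``, ``outside_pair_scope``.
    """
    t = transcripts[pair.transcript_id]
    cons = {
        role: consequence_for_isoform(v, pair, role, transcripts, genome)
        for role in ("annotated", "alternative")
    }
    ann, alt = cons["annotated"], cons["alternative"]
    is_ext = pair.pair_type == "extension"
    long_c, short_c = (alt, ann) if is_ext else (ann, alt)

    near = pair.alternative.codon != "ATG"
    category = "outside_pair_scope"
    ext_gen = False
    if ann.consequence == "non_coding" and alt.consequence == "non_coding":
        category = "outside_pair_scope"
    elif alt.consequence == "start_loss" and ann.consequence != "start_loss":
        if not near or near_cognate_start_loss:
            category = "alternative_start_loss"
        elif ann.consequence not in ("upstream_of_start", "non_coding", "synonymous"):
            category = "shared"  # near-cognate start hit, default AUG-only policy
        else:
            category = "outside_pair_scope"
    elif (
        long_c.consequence in LOF_CONSEQUENCES
        and short_c.consequence == "upstream_of_start"
    ):
        category = "alternative_only_LoF" if is_ext else "annotated_only_LoF"
        ext_gen = is_ext
    elif long_c.consequence == "missense" and short_c.consequence == "upstream_of_start":
        category = "isoform_specific_missense"
        ext_gen = is_ext
    elif (
        long_c.consequence in _PROTEIN_AFFECTING
        and short_c.consequence in _PROTEIN_AFFECTING
    ):
        category = "shared"

    # advisory: protein-preserving variant inside a Kozak window (-6..+4)
    kozak = False
    app = apply_variant(t, genome, v)
    if app.applicable and ann.consequence in ("upstream_of_start", "synonymous") and \
            alt.consequence in ("upstream_of_start", "synonymous"):
        f_lo, f_hi = (app.t_lo, app.t_hi) if app.t_hi > app.t_lo else (app.t_lo - 1, app.t_lo)
        for s0 in (t.cds_tstart, pair.alt_tpos):
            if f_lo < s0 + 4 and f_hi > s0 - 6:
                kozak = True
    return ISACall(
        variant=v,
        gene_id=pair.gene_id,
        pair_type=pair.pair_type,
        category=category,
        consequences=cons,
        kozak_flag=kozak,
        near_cognate_alt=near and alt.consequence == "start_loss",
        extension_generalized=ext_gen,
    )


def intersect_alt_starts(
    variants: list[VariantRecord],
    alt_starts: list[tuple[str, int, int, object]],
) -> list[tuple[VariantRecord, object]]:
    """Overlap variants with alternative start-codon intervals.

    ``alt_starts``: (contig, start, end, payload) with half-open 3-nt
    intervals.  SNV footprints are 1 base, deletions the deleted span,
    insertions the single base after which insertion occurs.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, s, e, payload in alt_starts:
        trees.setdefault(contig, IntervalTree()).addi(s, e, payload)
    hits: list[tuple[VariantRecord, object]] = []
    for v in variants:
        tree = trees.get(v.contig)
        if tree is None:
            continue
        lo, hi = v.footprint
        for iv in sorted(tree.overlap(lo, hi)):
            hits.append((v, iv.data))
    return hits


# ---------------------------------------------------------------------------
# Reporting


def isa_report(calls: list[ISACall]) -> dict:
    """Per-gene and global tallies by category and molecular impact class."""
    global_cat = {c: 0 for c in ISA_CATEGORIES}
    global_impact: dict[str, int] = {}
    per_gene: dict[str, dict[str, int]] = {}
    for call in calls:
        global_cat[call.category] += 1
        is_ext = call.pair_type == "extension"
        impact = call.consequences["alternative" if is_ext else "annotated"].consequence
        global_impact[impact] = global_impact.get(impact, 0) + 1
        g = per_gene.setdefault(call.gene_id, {c: 0 for c in ISA_CATEGORIES})
        g[call.category] += 1
    return {
        "n_calls": len(calls),
        "by_category": global_cat,
        "by_impact": dict(sorted(global_impact.items())),
        "per_gene": {g: per_gene[g] for g in sorted(per_gene)},
    }


def write_isa_table(calls: list[ISACall], path) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "contig", "pos", "ref", "alt", "gene_id", "pair_type", "category",
                "annotated_consequence", "annotated_c", "annotated_p",
                "alternative_consequence", "alternative_p",
                "kozak_flag", "near_cognate_alt", "extension_generalized",
                "significance", "condition",
            ]
        )
        for call in sorted(
            calls,
            key=lambda c: (c.variant.contig, c.variant.pos0, c.variant.nref,
                           c.variant.nalt, c.gene_id, c.pair_type),
        ):
            v, ann, alt = call.variant, call.consequences["annotated"], call.consequences["alternative"]
            w.writerow(
                [
                    v.contig, v.pos, v.ref, v.alt, call.gene_id, call.pair_type,
                    call.category,
                    ann.consequence, ann.c_notation, ann.p_notation,
                    alt.consequence, alt.p_notation,
                    int(call.kozak_flag), int(call.near_cognate_alt),
                    int(call.extension_generalized),
                    v.significance, v.condition,
                ]
            )


def write_isa_report(report: dict, tsv_path, json_path) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(tsv_path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id"] + list(ISA_CATEGORIES))
        for gene, counts in report["per_gene"].items():
            w.writerow([gene] + [counts[c] for c in ISA_CATEGORIES])
        w.writerow(["TOTAL"] + [report["by_category"][c] for c in ISA_CATEGORIES])
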