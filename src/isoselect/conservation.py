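"""Start-codon conservation summaries and Kozak-context utilities.

Per-base conservation (PhyloP-style) comes in as bedGraph or wiggle; a start
codon's conservation is the arithmetic mean over its 3 bases, withheld when
any base lacks a score.  Kozak strength uses the field-standard heuristic:
a purine at -3 and G at +4 make a strong context, exactly one of the two an
adequate one, neither a weak one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass


class ConservationError(ValueError):
    pass


class ConservationTrack:
    """Sparse per-base conservation scores: contig -> {0-based position: score}.

    Missing positions are distinguishable from a score of 0.
    """

    def __init__(self, scores: dict[str, dict[int, float]] | None = None):
        self._scores: dict[str, dict[int, float]] = scores or {}

    def get(self, contig: str, pos: int) -> float | None:
        return self._scores.get(contig, {}).get(pos)

    def set(self, contig: str, pos: int, score: float) -> None:
        self._scores.setdefault(contig, {})[pos] = score

    def __len__(self) -> int:
        return sum(len(d) for d in self._scores.values())

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        """bedGraph: chrom, start, end (0-based half-open), value."""
        track = cls()
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ConservationError(f"{path}:{ln}: expected 4 bedGraph columns")
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                for pos in range(start, end):
                    track.set(chrom, pos, value)
        return track

    @classmethod
    def from_wig(cls, path) -> "ConservationTrack":
        """Fixed-step and variable-step wiggle (1-based starts, per UCSC)."""
        track = cls()
        mode = chrom = None
        pos = step = span = 1
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                if line.startswith("fixedStep") or line.startswith("variableStep"):
                    fields = dict(
                        kv.split("=", 1) for kv in line.split()[1:]
                    )
                    mode = line.split()[0]
                    chrom = fields["chrom"]
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    pos = int(fields.get("start", 1)) - 1
                    continue
                if mode is None:
                    raise ConservationError(f"{path}:{ln}: data before a step header")
                if mode == "fixedStep":
                    value = float(line)
                    for k in range(span):
                        track.set(chrom, pos + k, value)
                    pos += step
                else:
                    p1, value = line.split()
                    p0 = int(p1) - 1
                    for k in range(span):
                        track.set(chrom, p0 + k, float(value))
        return track


@dataclass
class ConservationSummary:
    mean: float | None
    complete: bool
    n_scored: int


def start_codon_conservation(
    track: ConservationTrack, contig: str, codon_start: int, codon_end: int
) -> ConservationSummary:
    """Mean conservation over a start codon's 3 bases.

    Any missing base flags the summary incomplete and the partial mean is
    withheld (``mean`` is None).
    """
    if codon_end - codon_start != 3:
        raise ConservationError(
            f"start codon interval must be 3 nt (got [{codon_start}, {codon_end}))"
        )
    scores = [track.get(contig, p) for p in range(codon_start, codon_end)]
    present = [s for s in scores if s is not None]
    if len(present) < 3:
        return ConservationSummary(None, False, len(present))
    return ConservationSummary(sum(present) / 3.0, True, 3)


# ---------------------------------------------------------------------------
# Kozak context


@dataclass
class KozakContext:
    """The -6..+4 context of a start codon on a spliced transcript.

    ``window`` is 10 nt (6 upstream bases, the codon, the +4 base) when fully
    inside the transcript; shorter windows are flagged ``truncated`` and left
    unclassified.
    """

    window: str
    start_codon: str
    strength: str | None  # strong | adequate | weak | None when truncated
    truncated: bool


#: Optimal Kozak hexamer used when optimising a start-codon context.
OPTIMAL_KOZAK_UPSTREAM = "GCCACC"


def kozak_context(transcript_seq: str, start_pos: int) -> KozakContext:
    """Extract and classify the Kozak context at ``start_pos`` (0-based
    position of the start codon's first base on the spliced transcript)."""
    if not (0 <= start_pos <= len(transcript_seq) - 3):
        raise ConservationError(f"start position {start_pos} outside transcript")
    up = transcript_seq[max(0, start_pos - 6) : start_pos]
    codon = transcript_seq[start_pos : start_pos + 3]
    plus4 = transcript_seq[start_pos + 3 : start_pos + 4]
    window = up + codon + plus4
    truncated = len(up) < 6 or not plus4
    if len(up) >= 3 and plus4:
        minus3_purine = up[-3] in "AG"
        plus4_g = plus4 == "G"
        if minus3_purine and plus4_g:
            strength = "strong"
        elif minus3_purine or plus4_g:
            strength = "adequate"
        else:
            strength = "weak"
    else:
        strength = None
    return KozakContext(window, codon, strength, truncated)


def optimize_kozak(transcript_seq: str, start_pos: int) -> str:
    """Replace the 6 bases upstream of the start codon with GCCACC, keeping
    the start codon and the +4 base (hence the protein) unchanged."""
    if start_pos < 6:
        raise ConservationError(
            f"need 6 nt upstream of the start codon (start at {start_pos})"
        )
    if start_pos > len(transcript_seq) - 3:
        raise ConservationError(f"start position {start_pos} outside transcript")
    return (
        transcript_seq[: start_pos - 6]
        + OPTIMAL_KOZAK_UPSTREAM
        + transcript_seq[start_pos:]
    )


NEAR_COGNATE_NOTE = (
    "near-cognate start: codon identity changes between species can depress "
    "PhyloP despite conserved usage"
)


def write_conservation_table(rows: list[dict], path) -> None:
    """TSV keyed by gene/orf_type with per-start conservation and Kozak calls.

    Row keys: gene_id, orf_type, codon, contig, codon_start, codon_end,
    mean_phylop, complete, kozak_strength, note.
    """
    cols = [
        "gene_id", "orf_type", "codon", "contig", "codon_start", "codon_end",
        "mean_phylop", "complete", "kozak_strength", "note",
    ]
    with open(path, "w") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t", lineterminator="\n")
        w.writeheader()
        for row in sorted(rows, key=lambda r: (r["gene_id"], r["orf_type"])):
            w.writerow({k: row.get(k, "") for k in cols})
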