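"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's transcript-space editing and
consequence machinery: translation goes through Biopython, mutation is done
by genomic exon-string surgery, and the ISA category is re-derived from
whole-protein comparisons.
"""

from __future__ import annotations

from Bio.Seq import Seq

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def oracle_translate(nt: str) -> str:
    """Reference translation: standard code, stop-terminated, initiator Met."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(trimmed).translate(to_stop=True))
    if not aa:
        return ""
    return "M" + aa[1:]


def oracle_orf_type(tpos: int, seq: str, cds_start: int, cds_end: int) -> str:
    """Brute-force ORF typing by translating from the TIS and comparing stops."""
    if tpos == cds_start:
        return "annotated"
    if tpos > cds_start:
        if (tpos - cds_start) % 3 == 0 and tpos < cds_end - 3:
            return "truncation"
        return "other"
    if (cds_start - tpos) % 3 != 0:
        return "uORF"
    upstream = seq[tpos:cds_start]
    prot = str(Seq(upstream).translate(to_stop=True))
    if 3 * len(prot) < len(upstream):  # hit a stop before the annotated start
        return "uORF"
    return "extension"


def mutate_spliced(genome, t, v):
    """Mutate the spliced transcript by exon-string surgery in genomic space.

    Returns (mutated_spliced, t_lo, t_hi, delta) in wild-type transcript
    coordinates; None when the variant does not touch an exon; the string
    'unsupported' when it straddles an exon boundary.
    """
    exs = list(t.exons)
    seqs = [genome.fetch(t.contig, s, e) for s, e in exs]
    if v.nref:
        lo, hi = v.pos0, v.pos0 + len(v.nref)
        touching = [i for i, (s, e) in enumerate(exs) if s < hi and lo < e]
        if not touching:
            return None
        if len(touching) > 1:
            return "unsupported"
        i = touching[0]
        s, e = exs[i]
        if lo < s or hi > e:
            return "unsupported"
        local = lo - s
        seqs[i] = seqs[i][:local] + v.nalt + seqs[i][local + len(v.nref):]
        tps = sorted(t.genomic_to_tpos(g) for g in range(lo, hi))
        t_lo, t_hi = tps[0], tps[-1] + 1
        if t_hi - t_lo != len(v.nref):
            return "unsupported"
    else:
        interior = [i for i, (s, e) in enumerate(exs) if s < v.pos0 < e]
        if not interior:
            near = any(s <= v.pos0 - 1 < e or s <= v.pos0 < e for s, e in exs)
            return "unsupported" if near else None
        i = interior[0]
        s, e = exs[i]
        local = v.pos0 - s
        seqs[i] = seqs[i][:local] + v.nalt + seqs[i][local:]
        p1 = t.genomic_to_tpos(v.pos0 - 1)
        p2 = t.genomic_to_tpos(v.pos0)
        if abs(p1 - p2) != 1:
            return "unsupported"
        t_lo = t_hi = max(p1, p2)
    cat = "".join(seqs)
    mut = cat if t.strand == "+" else rc(cat)
    return mut, t_lo, t_hi, len(v.nalt) - len(v.nref)


def _start_effect(wt, mut, s, t_lo, t_hi, delta):
    """(mapped start position or None, start codon lost?)."""
    if t_hi <= s:
        s2 = s + delta
    elif t_lo >= s + 3:
        s2 = s
    elif delta == 0:
        s2 = s
    elif t_lo <= s < t_hi:
        return None, True  # first codon base deleted
    else:
        s2 = s  # insertion inside the codon; content check below decides
    if mut[s2 : s2 + 3] != wt[s : s + 3]:
        return s2, True
    return s2, False


def oracle_category(v, pair, transcripts, genome, near_cognate_start_loss=False):
    """Brute-force ISA category: mutate, translate from each position-mapped
    start, compare whole proteins, then apply the category rules."""
    t = transcripts[pair.transcript_id]
    wt = t.spliced_sequence(genome)
    res = mutate_spliced(genome, t, v)
    if res == "unsupported":
        return "unsupported"
    if res is None:
        return "outside_pair_scope"
    mut, t_lo, t_hi, delta = res

    roles = {}
    starts = {"annotated": t.cds_tstart, "alternative": pair.alt_tpos}
    for role, s in starts.items():
        s2, lost = _start_effect(wt, mut, s, t_lo, t_hi, delta)
        if lost:
            roles[role] = {"lost": True, "changed": True, "lof": False,
                           "upstream": False}
            continue
        wt_p = oracle_translate(wt[s:])
        mut_p = oracle_translate(mut[s2:])
        changed = mut_p != wt_p
        lof = changed and (
            (delta % 3 != 0 and t_hi > s)
            or (len(mut_p) < len(wt_p) and wt_p.startswith(mut_p))
        )
        roles[role] = {"lost": False, "changed": changed, "lof": lof,
                       "upstream": not changed and t_hi <= s}
    ann, alt = roles["annotated"], roles["alternative"]
    is_ext = pair.pair_type == "extension"
    long_r, short_r = (alt, ann) if is_ext else (ann, alt)
    near = pair.alternative.codon != "ATG"

    if alt["lost"] and not ann["lost"]:
        if not near or near_cognate_start_loss:
            return "alternative_start_loss"
        return "shared" if ann["changed"] else "outside_pair_scope"
    if long_r["lof"] and not short_r["changed"] and not short_r["lost"]:
        return "alternative_only_LoF" if is_ext else "annotated_only_LoF"
    if (long_r["changed"] and not long_r["lof"] and not long_r["lost"]
            and not short_r["changed"]):
        return "isoform_specific_missense"
    if (ann["changed"] or ann["lost"]) and (alt["changed"] or alt["lost"]):
        return "shared"
    return "outside_pair_scope"
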