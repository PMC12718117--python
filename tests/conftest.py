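from dataclasses import dataclass

import pytest

import isoselect as iso


@dataclass
class Bundle:
    sim: iso.SimBundle
    records: list
    pairs: list

    @property
    def genome(self):
        return self.sim.genome

    @property
    def transcripts(self):
        return self.sim.transcripts

    def pair(self, gene_id, pair_type="truncation"):
        for p in self.pairs:
            if p.gene_id == gene_id and p.pair_type == pair_type:
                return p
        raise KeyError((gene_id, pair_type))


def _bundle(sim: iso.SimBundle) -> Bundle:
    records = iso.classify_catalog(sim.tis_records, sim.transcripts, sim.genome)
    pairs = iso.build_isoform_pairs(records, sim.transcripts, sim.genome)
    return Bundle(sim, records, pairs)


@pytest.fixture(scope="session")
def micro() -> Bundle:
    """TRNT1/NAXE-style worked micro-fixture."""
    return _bundle(iso.trnt1_like_fixture())


@pytest.fixture(scope="session")
def sim() -> Bundle:
    """Default synthetic cohort (seed 0)."""
    return _bundle(iso.simulate(iso.SimConfig(seed=0)))


def make_transcript(
    seq_by_contig=None,
    exons=((0, 60),),
    strand="+",
    cds=(9, 45),
    contig="chr1",
    tid="T1",
    gene="G1",
    expression=1.0,
):
    """Small helper for hand-built transcript fixtures."""
    model = iso.TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        contig=contig,
        strand=strand,
        exons=tuple(exons),
        cds_genomic=cds,
        expression=expression,
    )
    genome = iso.GenomeSequence(seq_by_contig) if seq_by_contig else None
    return model, genome
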