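"""Localization predictions, differential calls and transition counting."""

import itertools

import pytest

import isoselect as iso
from isoselect.localization import (
    COMPARTMENTS,
    LocalizationError,
    LocalizationPrediction,
    TransitionTable,
)


def pred(*labels, **probs):
    base = {c: 0.05 for c in COMPARTMENTS}
    for lab in labels:
        base[lab] = 0.9
    base.update(probs)
    return LocalizationPrediction("x", frozenset(labels), base)


class TestPrediction:
    def test_empty_label_set_rejected(self):
        with pytest.raises(LocalizationError, match="empty"):
            LocalizationPrediction("x", frozenset(), {c: 0.1 for c in COMPARTMENTS})

    def test_unknown_label_rejected(self):
        with pytest.raises(LocalizationError, match="Cytoskeleton"):
            pred("Cytoskeleton")

    def test_probability_required_for_every_compartment(self):
        with pytest.raises(LocalizationError, match="missing"):
            LocalizationPrediction("x", frozenset({"Nucleus"}), {"Nucleus": 0.9})


class TestReadPredictions:
    def _write(self, tmp_path, rows):
        path = tmp_path / "p.tsv"
        header = "proteoform_id\tlabels\t" + "\t".join(COMPARTMENTS)
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def _row(self, pid, labels, mito=0.05):
        probs = ["0.05"] * len(COMPARTMENTS)
        probs[COMPARTMENTS.index("Mitochondrion")] = str(mito)
        return f"{pid}\t{labels}\t" + "\t".join(probs)

    def test_two_rows_two_predictions(self, tmp_path):
        path = self._write(
            tmp_path, [self._row("a", "Mitochondrion", 0.9), self._row("b", "Cytoplasm")]
        )
        preds, missing = iso.read_predictions(path)
        assert set(preds) == {"a", "b"}
        assert preds["a"].labels == {"Mitochondrion"}
        assert missing == []

    def test_duplicate_id_rejected(self, tmp_path):
        path = self._write(tmp_path, [self._row("a", "Cytoplasm")] * 2)
        with pytest.raises(LocalizationError, match="duplicate"):
            iso.read_predictions(path)

    def test_unknown_label_rejected(self, tmp_path):
        path = self._write(tmp_path, [self._row("a", "Cytoskeleton")])
        with pytest.raises(LocalizationError):
            iso.read_predictions(path)

    def test_missing_ids_reported(self, tmp_path):
        path = self._write(tmp_path, [self._row("a", "Cytoplasm")])
        _, missing = iso.read_predictions(path, expected_ids={"a", "b"})
        assert missing == ["b"]

    def test_labels_thresholded_from_probabilities_when_absent(self, tmp_path):
        path = self._write(tmp_path, [self._row("a", "", 0.9)])
        preds, _ = iso.read_predictions(path)
        assert preds["a"].labels == {"Mitochondrion"}

    def test_write_read_roundtrip(self, tmp_path, sim):
        preds = {}
        for pair in sim.pairs:
            ann, alt = iso.build_pair_proteoforms(pair, sim.transcripts, sim.genome)
            for p in (ann, alt):
                preds[p.proteoform_id] = iso.fixture_predictor(
                    p.sequence, p.proteoform_id
                )
        path = tmp_path / "preds.tsv"
        from isoselect.localization import write_predictions

        write_predictions(preds, path)
        back, missing = iso.read_predictions(path, expected_ids=set(preds))
        assert not missing
        for pid in preds:
            assert back[pid].labels == preds[pid].labels


class TestFixturePredictor:
    def test_planted_motifs_recognised(self):
        assert iso.fixture_predictor("M" + "R" * 6 + "G" * 20).labels == {
            "Mitochondrion"
        }
        assert iso.fixture_predictor("M" + "K" * 6 + "G" * 20).labels == {"Nucleus"}
        assert iso.fixture_predictor("M" + "L" * 14 + "G" * 20).labels == {
            "Endoplasmic reticulum"
        }

    def test_no_motif_defaults_to_cytoplasm(self):
        assert iso.fixture_predictor("M" + "G" * 30).labels == {"Cytoplasm"}

    def test_deterministic(self):
        a = iso.fixture_predictor("M" + "R" * 8 + "S" * 10)
        b = iso.fixture_predictor("M" + "R" * 8 + "S" * 10)
        assert a.labels == b.labels and a.probabilities == b.probabilities


class TestAverageNucleocytoplasmic:
    @pytest.mark.parametrize("nuc,cyt,expected", [(0.6, 0.2, 0.4), (0, 0, 0), (1, 1, 1)])
    def test_two_term_mean(self, nuc, cyt, expected):
        p = pred("Nucleus", Nucleus=nuc, Cytoplasm=cyt)
        assert iso.average_nucleocytoplasmic(p) == pytest.approx(expected)


class TestDifferentialCall:
    def test_mito_vs_nucleocytosolic_is_differential(self):
        assert iso.differential_call(pred("Mitochondrion"), pred("Cytoplasm", "Nucleus"))

    def test_identical_sets_are_not(self):
        assert not iso.differential_call(pred("Cytoplasm"), pred("Cytoplasm"))

    def test_nucleus_vs_cytoplasm_collapses_away(self):
        assert not iso.differential_call(pred("Nucleus"), pred("Cytoplasm"))
        assert iso.differential_call(
            pred("Nucleus"), pred("Cytoplasm"), collapse_nucleocytoplasmic=False
        )

    def test_symmetric_and_reflexive_false(self):
        preds = [pred("Mitochondrion"), pred("Cytoplasm", "Nucleus"), pred("Golgi")]
        for a, b in itertools.product(preds, preds):
            assert iso.differential_call(a, b) == iso.differential_call(b, a)
        for a in preds:
            assert not iso.differential_call(a, a)


class TestCountTransitions:
    def test_single_to_double(self):
        t = iso.count_transitions([(pred("Mitochondrion"), pred("Cytoplasm", "Nucleus"))])
        assert t.counts == {
            ("Mitochondrion", "Cytoplasm"): 1,
            ("Mitochondrion", "Nucleus"): 1,
        }

    def test_double_to_single(self):
        t = iso.count_transitions([(pred("Cytoplasm", "Nucleus"), pred("Mitochondrion"))])
        assert t.counts == {
            ("Cytoplasm", "Mitochondrion"): 1,
            ("Nucleus", "Mitochondrion"): 1,
        }

    def test_double_to_double_full_cross_product(self):
        t = iso.count_transitions(
            [(pred("Mitochondrion", "Nucleus"), pred("Cytoplasm", "Nucleus"))]
        )
        assert t.counts == {
            ("Mitochondrion", "Cytoplasm"): 1,
            ("Mitochondrion", "Nucleus"): 1,
            ("Nucleus", "Cytoplasm"): 1,
            ("Nucleus", "Nucleus"): 1,
        }

    def test_identical_sets_record_only_self_transitions(self):
        t = iso.count_transitions(
            [(pred("Cytoplasm", "Nucleus"), pred("Cytoplasm", "Nucleus"))]
        )
        assert t.counts == {
            ("Cytoplasm", "Cytoplasm"): 1,
            ("Nucleus", "Nucleus"): 1,
        }

    def test_cardinality_rule(self):
        """|A| self-transitions when A == B, else |A| * |B|."""
        pool = ["Mitochondrion", "Nucleus", "Cytoplasm", "Golgi"]
        for na in (1, 2, 3):
            for nb in (1, 2, 3):
                a, b = pred(*pool[:na]), pred(*pool[1 : nb + 1])
                t = iso.count_transitions([(a, b)])
                expected = na if a.labels == b.labels else na * nb
                assert t.total == expected

    def test_aggregation_is_sum_of_per_pair_tables(self):
        pairs = [
            (pred("Mitochondrion"), pred("Cytoplasm", "Nucleus")),
            (pred("Cytoplasm"), pred("Cytoplasm")),
            (pred("Golgi", "Nucleus"), pred("Mitochondrion")),
        ]
        whole = iso.count_transitions(pairs)
        acc = TransitionTable()
        for p in pairs:
            acc.update(iso.count_transitions([p]))
        assert whole.counts == acc.counts

    def test_missing_prediction_is_an_error(self):
        with pytest.raises(LocalizationError):
            iso.count_transitions([(pred("Cytoplasm"), None)])

    def test_table_writers(self, tmp_path):
        t = iso.count_transitions([(pred("Mitochondrion"), pred("Cytoplasm"))])
        t.write(tmp_path / "t.tsv", tmp_path / "t.json")
        assert "Mitochondrion\tCytoplasm\t1" in (tmp_path / "t.tsv").read_text()
        import json

        obj = json.loads((tmp_path / "t.json").read_text())
        assert obj == [{"source": "Mitochondrion", "target": "Cytoplasm", "value": 1}]


class TestLocalizationChangeScreen:
    def test_motif_destroying_missense_is_flagged(self, micro):
        pair = micro.pair("NAXEL")
        v = next(v for v in micro.sim.variants if v.variant_id == "NAXEL_c16C_T")
        cc = iso.consequence_for_isoform(
            v, pair, "annotated", micro.transcripts, micro.genome
        )
        ann, _ = iso.build_pair_proteoforms(pair, micro.transcripts, micro.genome)
        entries = [("NAXEL_c16C_T", ann.sequence, cc.mutant_protein)]
        assert iso.localization_change_screen(entries) == [("NAXEL_c16C_T", True)]

    def test_silent_control_not_flagged(self, micro):
        ann, _ = iso.build_pair_proteoforms(
            micro.pair("NAXEL"), micro.transcripts, micro.genome
        )
        assert iso.localization_change_screen([("ctl", ann.sequence, ann.sequence)]) == [
            ("ctl", False)
        ]

    def test_empty_input(self):
        assert iso.localization_change_screen([]) == []
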