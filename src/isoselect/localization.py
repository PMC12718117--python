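"""Subcellular-localization comparison between isoform pairs.

The localization predictor itself (DeepLoc-class tooling) is an external
black box consumed through a file contract: a tab-separated table keyed by
proteoform_id with a comma-separated multi-label set and one probability
column per compartment.  A deterministic rule-based fixture predictor is
built in so the pipeline is testable offline; it recognises the sentinel
motifs planted by the synthetic-data generator and is not a reimplementation
of any published predictor.

Transition counting between an annotated/alternative pair follows the
cardinality rule: identical label sets yield one self-transition per label;
differing sets yield the full cross product annotated-label -> alternative-
label.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

COMPARTMENTS = (
    "Cytoplasm",
    "Nucleus",
    "Mitochondrion",
    "Endoplasmic reticulum",
    "Golgi",
    "Lysosome/Vacuole",
    "Peroxisome",
    "Cell membrane",
    "Extracellular",
    "Plastid",
)

_NUCLEOCYTO = frozenset({"Nucleus", "Cytoplasm"})
_NUCLEOCYTO_LABEL = "Nucleus/Cytoplasm"


class LocalizationError(ValueError):
    pass


@dataclass(frozen=True)
class LocalizationPrediction:
    proteoform_id: str
    labels: frozenset[str]
    probabilities: dict[str, float] = field(hash=False, default_factory=dict)

    def __post_init__(self):
        if not self.labels:
            raise LocalizationError(f"{self.proteoform_id}: empty label set")
        bad = set(self.labels) - set(COMPARTMENTS)
        if bad:
            raise LocalizationError(
                f"{self.proteoform_id}: unknown compartment label(s) {sorted(bad)}"
            )
        missing = set(COMPARTMENTS) - set(self.probabilities)
        if missing:
            raise LocalizationError(
                f"{self.proteoform_id}: missing probabilities for {sorted(missing)}"
            )
        for k, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise LocalizationError(f"{self.proteoform_id}: P({k})={p} outside [0,1]")


def read_predictions(
    path, expected_ids: set[str] | None = None
) -> tuple[dict[str, LocalizationPrediction], list[str]]:
    """Read a predictor output table.

    Columns: ``proteoform_id``, ``labels`` (comma-separated; optional if
    probabilities are supplied, in which case labels are thresholded at 0.5),
    plus one probability column per compartment.  Returns the predictions and
    the list of expected proteoform ids with no prediction.
    """
    df = pd.read_csv(path, sep="\t", dtype={"proteoform_id": str})
    if "proteoform_id" not in df.columns:
        raise LocalizationError(f"{path}: missing proteoform_id column")
    missing_cols = [c for c in COMPARTMENTS if c not in df.columns]
    if missing_cols:
        raise LocalizationError(f"{path}: missing probability columns {missing_cols}")
    preds: dict[str, LocalizationPrediction] = {}
    for row in df.to_dict("records"):
        pid = row["proteoform_id"]
        if pid in preds:
            raise LocalizationError(f"{path}: duplicate proteoform_id {pid!r}")
        probs = {c: float(row[c]) for c in COMPARTMENTS}
        raw = row.get("labels")
        if isinstance(raw, str) and raw.strip():
            labels = frozenset(x.strip() for x in raw.split(","))
        else:
            labels = frozenset(c for c, p in probs.items() if p >= 0.5)
            if not labels:
                labels = frozenset({max(probs, key=probs.get)})
        preds[pid] = LocalizationPrediction(pid, labels, probs)
    missing = sorted(expected_ids - set(preds)) if expected_ids else []
    for pid in missing:
        log.warning("no localization prediction for %s", pid)
    return preds, missing


def write_predictions(preds: dict[str, LocalizationPrediction], path) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["proteoform_id", "labels", *COMPARTMENTS])
        for pid in sorted(preds):
            p = preds[pid]
            w.writerow(
                [pid, ",".join(sorted(p.labels))]
                + [f"{p.probabilities[c]:.3f}" for c in COMPARTMENTS]
            )


# ---------------------------------------------------------------------------
# Built-in deterministic fixture predictor

_HYDROPHOBIC = frozenset("AILVFWCM")


def fixture_predictor(sequence: str, proteoform_id: str = "") -> LocalizationPrediction:
    """Deterministic rule-based stand-in for an external predictor.

    Looks at the 15 residues after the initiator Met: an arginine-rich block
    (>= 6 R) reads as a mitochondrial presequence, a lysine-rich block (>= 6 K)
    as a nuclear localization signal, a hydrophobic leader (>= 12 hydrophobic)
    as an ER signal peptide; anything else is cytoplasmic.
    """
    window = sequence[1:16]
    if window.count("R") >= 6:
        label = "Mitochondrion"
    elif window.count("K") >= 6:
        label = "Nucleus"
    elif sum(1 for a in window if a in _HYDROPHOBIC) >= 12:
        label = "Endoplasmic reticulum"
    else:
        label = "Cytoplasm"
    probs = {c: 0.05 for c in COMPARTMENTS}
    probs["Cytoplasm"] = 0.30
    probs["Nucleus"] = 0.30
    probs[label] = 0.85
    return LocalizationPrediction(proteoform_id or "anonymous", frozenset({label}), probs)


def average_nucleocytoplasmic(pred: LocalizationPrediction) -> float:
    """Mean of the nucleus and cytosol probabilities (plotted jointly because
    predictors poorly separate the two compartments)."""
    return (pred.probabilities["Nucleus"] + pred.probabilities["Cytoplasm"]) / 2.0


def _collapse(labels: frozenset[str]) -> frozenset[str]:
    if labels & _NUCLEOCYTO:
        return frozenset(labels - _NUCLEOCYTO | {_NUCLEOCYTO_LABEL})
    return labels


def differential_call(
    a: LocalizationPrediction,
    b: LocalizationPrediction,
    collapse_nucleocytoplasmic: bool = True,
) -> bool:
    """True when the two label sets differ.  With collapsing (default),
    Nucleus and Cytoplasm merge into one label first, so a pure
    nucleus<->cytosol difference is not called differential."""
    la, lb = a.labels, b.labels
    if collapse_nucleocytoplasmic:
        la, lb = _collapse(la), _collapse(lb)
    return la != lb


# ---------------------------------------------------------------------------
# Transition counting


@dataclass
class TransitionTable:
    counts: Counter = field(default_factory=Counter)

    def add_pair(
        self, annotated: LocalizationPrediction, alternative: LocalizationPrediction
    ) -> None:
        """Count transitions for one pair: identical label sets record one
        self-transition per label (no transitions across organelles);
        otherwise every (annotated label, alternative label) combination is a
        distinct transition."""
        a, b = annotated.labels, alternative.labels
        if a == b:
            for lab in a:
                self.counts[(lab, lab)] += 1
        else:
            for x in a:
                for y in b:
                    self.counts[(x, y)] += 1

    def update(self, other: "TransitionTable") -> None:
        self.counts.update(other.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"from": k[0], "to": k[1], "count": n}
            for k, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count"])

    def write(self, tsv_path, json_path=None) -> None:
        self.to_dataframe().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            obj = [
                {"source": k[0], "target": k[1], "value": n}
                for k, n in sorted(self.counts.items())
            ]
            with open(json_path, "w") as fh:
                json.dump(obj, fh, indent=2)
                fh.write("\n")


def count_transitions(
    pairs_with_predictions: list[tuple[LocalizationPrediction, LocalizationPrediction]],
) -> TransitionTable:
    """Aggregate transition counts over (annotated, alternative) prediction pairs."""
    table = TransitionTable()
    for ann, alt in pairs_with_predictions:
        if ann is None or alt is None:
            raise LocalizationError("missing prediction for one isoform of a pair")
        table.add_pair(ann, alt)
    return table


def localization_change_screen(
    entries: list[tuple[str, str, str]],
    predictor=fixture_predictor,
    collapse_nucleocytoplasmic: bool = True,
) -> list[tuple[str, bool]]:
    """Screen isoform-specific missense alleles for predicted localization
    changes of the affected isoform.

    ``entries``: (identifier, wild-type protein, mutant protein).  Returns
    (identifier, changed) with ``changed`` true when the predictor's label
    sets for wild type and mutant differ.
    """
    out = []
    for ident, wt, mut in entries:
        pw = predictor(wt, f"{ident}|wt")
        pm = predictor(mut, f"{ident}|mut")
        out.append((ident, differential_call(pw, pm, collapse_nucleocytoplasmic)))
    return out
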