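"""Binary essentiality prediction from scores and the five evaluation metrics.

A gene is called essential from its KO's E_score when one is available
(E_score >= tau_e) and from its P_score otherwise (P_score >= tau_p); the
experimental score takes strict priority, with P_score as supplementary
information. Against experimental labels, predictions are summarized by a
confusion matrix and sensitivity, specificity, precision, accuracy, and
F-measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .exceptions import ConfigError
from .ko_tables import ESSENTIAL, NONESSENTIAL, StrainGeneRecord
from .scoring import ScoreRecord, Thresholds

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f_measure")


@dataclass(frozen=True)
class PredictionRecord:
    locus_tag: str
    ko_id: str | None
    predicted: str  # essential | nonessential | unscored
    basis: str  # e_score | p_score | none
    conflict: bool = False  # the unused score disagrees with the call


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ConfigError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def predict(
    scores: dict[str, ScoreRecord],
    genes: list[StrainGeneRecord],
    thresholds: Thresholds | None = None,
    rule: str = "e_priority",
) -> list[PredictionRecord]:
    """Predict essentiality per gene from its KO's scores.

    ``e_priority`` (default): decide on E_score when present, else on P_score,
    else unscored. ``either``: essential when either available score clears
    its threshold. Genes without a KO, or whose KO has neither score, are
    unscored. A prediction where the unused score would have decided the other
    way is flagged for user review via ``conflict``.
    """
    if rule not in ("e_priority", "either"):
        raise ConfigError(f"unknown combination rule {rule!r}")
    thresholds = thresholds or Thresholds()
    out: list[PredictionRecord] = []
    for gene in genes:
        rec = scores.get(gene.ko_id) if gene.ko_id else None
        e = rec.e_score if rec else None
        p = rec.p_score if rec else None
        if e is None and p is None:
            out.append(
                PredictionRecord(gene.locus_tag, gene.ko_id, "unscored", "none")
            )
            continue
        e_call = None if e is None else e >= thresholds.tau_e
        p_call = None if p is None else p >= thresholds.tau_p
        if rule == "either":
            call = bool(e_call) or bool(p_call)
            basis = "e_score" if e is not None else "p_score"
        elif e_call is not None:
            call, basis = e_call, "e_score"
        else:
            call, basis = p_call, "p_score"
        conflict = e_call is not None and p_call is not None and e_call != p_call
        out.append(
            PredictionRecord(
                locus_tag=gene.locus_tag,
                ko_id=gene.ko_id,
                predicted="essential" if call else "nonessential",
                basis=basis,
                conflict=conflict,
            )
        )
    return out


def confusion(
    predictions: list[PredictionRecord],
    truth_labels: dict[str, str],
) -> ConfusionMatrix:
    """Tally predictions against experimental labels, joined on locus tag.

    Unscored genes are excluded; so are scored genes whose label is missing or
    unknown (with a warning).
    """
    tp = fn = tn = fp = 0
    for pred in predictions:
        if pred.predicted == "unscored":
            continue
        label = truth_labels.get(pred.locus_tag)
        if label not in (ESSENTIAL, NONESSENTIAL):
            logger.warning(
                "locus tag %s: no usable experimental label; excluded", pred.locus_tag
            )
            continue
        truth_essential = label == ESSENTIAL
        pred_essential = pred.predicted == "essential"
        if pred_essential and truth_essential:
            tp += 1
        elif pred_essential:
            fp += 1
        elif truth_essential:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, precision, accuracy and F-measure.

    A metric whose denominator is zero is reported absent (None); the
    F-measure needs both sensitivity and precision defined and non-zero in sum.
    """
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    if sens is not None and prec is not None and (sens + prec) > 0:
        f = 2 * sens * prec / (sens + prec)
    else:
        f = None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f_measure": f,
    }
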