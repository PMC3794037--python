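"""Agreement between paired field and imagery cell statuses.

The comparison treats the field survey as truth and the imagery survey
as a binary classifier: imagery PRESENCE is the positive class, imagery
ABSENCE and INDISTINCT the negative class (a doubtful sighting is
scored as absence), and imagery NO_DATA cells are excluded from the
analysis altogether.  From the resulting TP/FP/FN/TN counts the four
point statistics are

    sensitivity = TP / P          P = TP + FN
    specificity = TN / N          N = TN + FP
    accuracy    = (TP + TN) / (P + N)
    MCC         = (TP*TN - FP*FN) /
                  sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC, the Matthews / phi coefficient, equals the Pearson correlation of
the two underlying 0/1 vectors; it ranges over [-1, 1] with 0 for
chance-level agreement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import pandas as pd

from .survey import CellStatus, Status

__all__ = [
    "Binary",
    "ConfusionMatrix",
    "AgreementMetrics",
    "resolve_binary",
    "confusion",
    "confusion_from_table",
    "metrics",
    "round_report",
]


class Binary(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class AgreementMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def resolve_binary(status: CellStatus | Status) -> Binary:
    """Collapse a four-valued imagery status to the binary classes.

    INDISTINCT counts as negative (a doubtful sighting is scored as
    absence); NO_DATA cells are excluded from the analysis.
    """
    s = status.status if isinstance(status, CellStatus) else status
    if not isinstance(s, Status):
        try:
            s = Status(s)
        except ValueError:
            raise ValueError(f"unknown status value {s!r}") from None
    if s is Status.PRESENCE:
        return Binary.POSITIVE
    if s in (Status.ABSENCE, Status.INDISTINCT):
        return Binary.NEGATIVE
    return Binary.EXCLUDED


def confusion(
    field: Sequence[CellStatus], imagery: Sequence[CellStatus]
) -> ConfusionMatrix:
    """Tally the confusion matrix over the analyzed (non-excluded) cells.

    Field statuses must be binary (the field protocol cannot produce
    NO_DATA or INDISTINCT); both lists must cover the same cell ids.
    """
    fmap = {c.cell_id: c for c in field}
    imap = {c.cell_id: c for c in imagery}
    if len(fmap) != len(field) or len(imap) != len(imagery):
        raise ValueError("duplicate cell ids in status list")
    for cid in fmap:
        if cid not in imap:
            raise ValueError(f"cell {cid} present in field but missing from imagery")
    for cid in imap:
        if cid not in fmap:
            raise ValueError(f"cell {cid} present in imagery but missing from field")
    tp = fp = fn = tn = 0
    for cid, f in fmap.items():
        if f.status not in (Status.PRESENCE, Status.ABSENCE):
            raise ValueError(
                f"field status for cell {cid} is {f.status.value}; the field "
                "protocol only produces PRESENCE or ABSENCE"
            )
        pred = resolve_binary(imap[cid])
        if pred is Binary.EXCLUDED:
            continue
        truth_pos = f.status is Status.PRESENCE
        pred_pos = pred is Binary.POSITIVE
        if truth_pos and pred_pos:
            tp += 1
        elif truth_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_from_table(table: pd.DataFrame) -> ConfusionMatrix:
    """Confusion matrix from a paired-status table.

    Expects columns ``cell_id``, ``field_status``, ``imagery_status``
    (the CSV interchange format).
    """
    field = [
        CellStatus(cell_id=cid, status=Status(s))
        for cid, s in zip(table["cell_id"], table["field_status"])
    ]
    imagery = [
        CellStatus(cell_id=cid, status=Status(s))
        for cid, s in zip(table["cell_id"], table["imagery_status"])
    ]
    return confusion(field, imagery)


def metrics(cm: ConfusionMatrix) -> AgreementMetrics:
    """The four agreement statistics of a confusion matrix.

    With no positive (or negative) truth cells the sensitivity (resp.
    specificity) is undefined and reported as nan with a warning.  A
    zero MCC denominator (any all-zero margin) yields 0 by convention,
    also flagged.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix: no analyzed cells")
    if cm.p == 0:
        warnings.warn("no positive cells: sensitivity undefined (nan)", stacklevel=2)
        sens = float("nan")
    else:
        sens = cm.tp / cm.p
    if cm.n == 0:
        warnings.warn("no negative cells: specificity undefined (nan)", stacklevel=2)
        spec = float("nan")
    else:
        spec = cm.tn / cm.n
    acc = (cm.tp + cm.tn) / cm.total
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if den == 0:
        warnings.warn("MCC denominator is 0; reporting 0 by convention", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(den)
    return AgreementMetrics(sensitivity=sens, specificity=spec, accuracy=acc, mcc=mcc)


def round_report(value: float, digits: int = 3) -> float:
    """Half-up rounding to the report precision (3 decimals by default)."""
    if math.isnan(value):
        return value
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
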