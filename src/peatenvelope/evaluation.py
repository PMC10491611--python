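"""Presence/absence map evaluation: sensitivity, accuracy, Cohen's kappa.

With TP/FP/FN/TN the confusion counts over jointly defined cells:

    sensitivity = TP / (TP + FN)
    accuracy    = (TP + TN) / N          (= observed agreement Po)
    Pe          = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2
    kappa       = (Po - Pe) / (1 - Pe)

Kappa is the standard two-rater chance-corrected agreement with
marginal-product expected agreement; it is 0 for any constant predictor
regardless of prevalence, which is what makes it the informative metric
when presences are rare.  Undefined metrics (e.g. sensitivity with no
observed presences, kappa at Pe = 1) are reported as ``None`` with a
reason code, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies over jointly defined cells."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n


@dataclass
class EvalMetrics:
    """Sensitivity, accuracy and kappa with their agreement components."""

    counts: ConfusionCounts
    sensitivity: float | None
    accuracy: float
    po: float
    pe: float
    kappa: float | None
    undefined_reasons: dict[str, str]

    def to_dict(self) -> dict:
        c = self.counts
        return {"N": c.n, "TP": c.tp, "FP": c.fp, "FN": c.fn, "TN": c.tn,
                "sensitivity": self.sensitivity, "accuracy": self.accuracy,
                "kappa": self.kappa, "Po": self.po, "Pe": self.pe,
                "undefined": self.undefined_reasons}


def confusion(predicted, observed, valid=None) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between boolean presence arrays.

    ``valid`` marks jointly defined cells; cells outside it are excluded
    and counted in ``n_excluded``.
    """
    p = np.asarray(predicted, dtype=bool)
    o = np.asarray(observed, dtype=bool)
    if p.shape != o.shape:
        raise ValueError("predicted and observed shapes differ")
    if valid is None:
        valid = np.ones(p.shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
    n_excluded = int((~valid).sum())
    p, o = p[valid], o[valid]
    if p.size == 0:
        raise ValueError("no jointly defined cells to evaluate")
    return ConfusionCounts(
        tp=int((p & o).sum()), fp=int((p & ~o).sum()),
        fn=int((~p & o).sum()), tn=int((~p & ~o).sum()),
        n_excluded=n_excluded)


def evaluate(counts: ConfusionCounts) -> EvalMetrics:
    """Compute the three evaluation metrics from confusion counts."""
    n = counts.n
    if n <= 0:
        raise ValueError("cannot evaluate empty confusion counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    undefined: dict[str, str] = {}

    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = None
        undefined["sensitivity"] = "no observed presences (TP + FN = 0)"

    po = accuracy = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe < 1.0:
        kappa = (po - pe) / (1.0 - pe)
    else:
        kappa = None
        undefined["kappa"] = "expected agreement Pe = 1 (degenerate margins)"

    return EvalMetrics(counts=counts, sensitivity=sensitivity,
                       accuracy=accuracy, po=po, pe=pe, kappa=kappa,
                       undefined_reasons=undefined)


def evaluate_masks(predicted, observed, valid=None) -> EvalMetrics:
    """Convenience: confusion + evaluate on PeatMask or boolean arrays."""
    p = getattr(predicted, "presence", predicted)
    o = getattr(observed, "presence", observed)
    return evaluate(confusion(p, o, valid=valid))
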