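"""Classification metrics for read- and site-level methylation calls:
accuracy, sensitivity, specificity, ROC AUC and AUPR."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class MetricReport:
    """Threshold metrics plus ranking metrics for one score/label set.

    ``auc``/``aupr`` are ``None`` (with ``undefined_reason``) when the
    labels contain a single class; the threshold metrics are still
    computed, with the empty-class rate reported as ``nan``.
    """

    acc: float
    sen: float
    spe: float
    auc: float | None
    aupr: float | None
    n_pos: int
    n_neg: int
    threshold: float
    undefined_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "auc": self.auc,
            "aupr": self.aupr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "threshold": self.threshold,
            "undefined_reason": self.undefined_reason,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join("NA" if v is None else str(v) for v in d.values()) + "\n")


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Compute ACC/SEN/SPE at ``threshold`` (score >= threshold is a positive
    call) and AUC/AUPR over the ranking.  Deterministic and tie-aware."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be equal-length non-empty 1-D arrays")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary")
    calls = s >= threshold
    tp = int(np.sum(calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    acc = (tp + tn) / y.size
    sen = tp / n_pos if n_pos else float("nan")
    spe = tn / n_neg if n_neg else float("nan")
    if n_pos and n_neg:
        auc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
        reason = None
    else:
        auc = aupr = None
        reason = "labels contain a single class; AUC/AUPR undefined"
    return MetricReport(acc, sen, spe, auc, aupr, n_pos, n_neg, threshold, reason)
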