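"""Confusion-matrix algebra and macro-averaged multiclass metrics.

The confusion matrix (CM) is the central diagnostic object of the whole
pipeline: per-fold CMs are summed into a cross-validated CM (CVCM), the CVCM
drives the similar-class grouping, and fine-grained CMs are projected onto
coarser label hierarchies (drug -> package type, drug -> similarity group)
for multi-level evaluation.

Orientation is fixed throughout: rows are the true class ``i``, columns the
predicted class ``j``, so ``counts[i, j]`` is the number of class-``i``
instances predicted as class ``j``.  Per class ``i``:

    TP_i = counts[i, i]
    FN_i = row_i sum  - TP_i      (class-i instances sent elsewhere)
    FP_i = column_i sum - TP_i    (other instances predicted as i)

Macro metrics average the per-class recall ``TP_i / (TP_i + FN_i)`` and
precision ``TP_i / (TP_i + FP_i)`` uniformly over classes; accuracy is the
diagonal mass over the total.  A class whose recall or precision is
undefined (zero support row / zero predicted column) contributes 0 to the
macro average and triggers a warning — the conservative convention.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "LabelMap",
    "build_cm",
    "aggregate_folds",
    "macro_metrics",
    "project",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix over an ordered label set (rows=true, cols=predicted)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels but counts side {counts.shape[0]}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts.astype(np.int64))
        self.counts.setflags(write=False)

    # -- derived quantities -------------------------------------------------

    @property
    def r(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def support(self) -> np.ndarray:
        """Row sums: number of true instances per class."""
        return self.counts.sum(axis=1)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: header row of labels, one labelled row per true class."""
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.counts):
            lines.append(lab + "\t" + "\t".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfusionMatrix":
        lines = Path(path).read_text().rstrip("\n").split("\n")
        header = lines[0].split("\t")[1:]
        rows, row_labels = [], []
        for line in lines[1:]:
            cells = line.split("\t")
            row_labels.append(cells[0])
            rows.append([int(v) for v in cells[1:]])
        if row_labels != header:
            raise ValueError("row labels do not match column labels")
        return cls(tuple(header), np.array(rows, dtype=np.int64))

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update("\x1f".join(self.labels).encode())
        h.update(self.counts.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class MetricsReport:
    """Macro-averaged metrics plus the per-class table they average."""

    macro_recall: float
    macro_precision: float
    macro_f1: float
    accuracy: float
    per_class: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MetricsReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            macro_recall=d["macro_recall"],
            macro_precision=d["macro_precision"],
            macro_f1=d["macro_f1"],
            accuracy=d["accuracy"],
            per_class=d.get("per_class", {}),
        )


class LabelMap(dict):
    """Total mapping from fine labels to coarse labels (e.g. drug -> package type).

    A plain dict with membership checks: looking up an unmapped fine label
    raises a labelled KeyError instead of silently failing downstream.
    """

    def __missing__(self, key):
        raise KeyError(f"fine label {key!r} has no coarse assignment")

    def coarse_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.values())))


def build_cm(
    true_labels: Sequence,
    predicted_labels: Sequence,
    labels: Sequence | None = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix from paired true/predicted label sequences.

    ``labels`` fixes the (ordered) label set; when omitted, the
    lexicographically sorted union of observed labels is used.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    if labels is None:
        labels = sorted(set(true_labels) | set(predicted_labels))
    labels = tuple(str(l) for l in labels)
    index = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        t, p = str(t), str(p)
        if t not in index:
            raise ValueError(f"true label {t!r} not in label set")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in label set")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels, counts)


def aggregate_folds(cms: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum of per-fold CMs sharing one ordered label set (the CVCM)."""
    cms = list(cms)
    if not cms:
        raise ValueError("no confusion matrices to aggregate")
    ref = cms[0]
    for cm in cms[1:]:
        if cm.labels != ref.labels:
            diff = set(cm.labels) ^ set(ref.labels)
            raise ValueError(
                f"label sets differ (symmetric difference: {sorted(diff)})"
                if diff
                else "label order differs between folds"
            )
    total = np.sum([cm.counts for cm in cms], axis=0)
    return ConfusionMatrix(ref.labels, total)


def macro_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Macro recall/precision/F1 and accuracy from a confusion matrix.

    macroR = (1/r) sum_i TP_i/(TP_i+FN_i); macroP likewise over columns;
    macroF1 is the harmonic mean of the two macro values; accuracy is
    trace/total.  Undefined per-class ratios contribute 0 (warned).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix (total count is zero)")
    tp = cm.tp().astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)

    per_class: dict[str, dict[str, float]] = {}
    recalls = np.zeros(cm.r)
    precisions = np.zeros(cm.r)
    for i, lab in enumerate(cm.labels):
        if row[i] > 0:
            recalls[i] = tp[i] / row[i]
        else:
            warnings.warn(
                f"class {lab!r} has zero support; recall set to 0", stacklevel=2
            )
        if col[i] > 0:
            precisions[i] = tp[i] / col[i]
        else:
            warnings.warn(
                f"class {lab!r} never predicted; precision set to 0", stacklevel=2
            )
        f1 = (
            2 * precisions[i] * recalls[i] / (precisions[i] + recalls[i])
            if precisions[i] + recalls[i] > 0
            else 0.0
        )
        per_class[lab] = {
            "recall": float(recalls[i]),
            "precision": float(precisions[i]),
            "f1": float(f1),
            "support": float(row[i]),
        }

    macro_r = float(recalls.mean())
    macro_p = float(precisions.mean())
    macro_f1 = (
        2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r > 0 else 0.0
    )
    return MetricsReport(
        macro_recall=macro_r,
        macro_precision=macro_p,
        macro_f1=float(macro_f1),
        accuracy=float(tp.sum() / cm.total),
        per_class=per_class,
    )


def project(cm: ConfusionMatrix, label_map: Mapping[str, str]) -> ConfusionMatrix:
    """Project a fine-label CM onto coarse labels.

    Coarse cell (p, q) accumulates every fine cell (i, j) with i in p and
    j in q; fine confusions within one coarse class therefore land on the
    coarse diagonal, so total mass is conserved and coarse accuracy can only
    rise.
    """
    for lab in cm.labels:
        if lab not in label_map:
            raise KeyError(f"fine label {lab!r} missing from label map")
    coarse = sorted({label_map[l] for l in cm.labels})
    cindex = {lab: k for k, lab in enumerate(coarse)}
    out = np.zeros((len(coarse), len(coarse)), dtype=np.int64)
    for i, li in enumerate(cm.labels):
        p = cindex[label_map[li]]
        for j, lj in enumerate(cm.labels):
            out[p, cindex[label_map[lj]]] += cm.counts[i, j]
    return ConfusionMatrix(tuple(coarse), out)
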