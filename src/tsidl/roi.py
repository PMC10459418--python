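"""Centered crop pyramid and per-group region-of-interest selection.

For each similarity group a square, centered window is chosen from a halving
ladder of candidate sides (N, N/2, N/4, N/8 — e.g. 2992/1496/748/374 on
full-resolution frames, 256/128/64/32 on desk-scale synthetic frames).
Cropping to that window before the backbone's input resize magnifies the
small central features (pill imprints, label text) that discriminate classes
within the group, while the residual group keeps the full frame.

Window convention: 0-based pixel indices, half-open ranges, center at
(floor(H/2), floor(W/2)); a side-``r`` window spans
``[c - floor(r/2), c - floor(r/2) + r)`` on each axis.  Crops copy pixels —
no resampling, no padding: a window larger than the frame is an error.

The expert-in-the-loop choice of the optimal side is replaced by (a) a
manual configuration mapping group -> side (the recorded expert choice) and
(b) an automated proxy selector that scores every candidate side with a
quick classifier on the group's own training/validation images and keeps
the best (ties broken toward the larger side).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CropPyramid",
    "CropSpec",
    "pyramid_sizes",
    "center_crop",
    "select_optimal_crop",
]


def pyramid_sizes(n: int, levels: int = 4) -> list[int]:
    """Halving ladder of window sides: ``floor(n / 2**k)`` for k = 0..levels-1."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if n < 2 ** (levels - 1):
        raise ValueError(
            f"frame side {n} too small for {levels} halving levels "
            f"(needs at least {2 ** (levels - 1)})"
        )
    return [n // (2**k) for k in range(levels)]


@dataclass(frozen=True)
class CropPyramid:
    """Candidate window sides for one frame size."""

    base_side: int
    levels: int = 4
    sides: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sides", tuple(pyramid_sizes(self.base_side, self.levels)))

    @property
    def center(self) -> tuple[int, int]:
        return (self.base_side // 2, self.base_side // 2)


@dataclass(frozen=True)
class CropSpec:
    """Chosen window side per similarity-group index; residual keeps full frame.

    ``sides[k]`` is the crop side for group k; a value of ``None`` (always
    used for the residual index) means identity — no cropping.
    """

    sides: Mapping[int, int | None]
    base_side: int
    levels: int = 4

    def side_for(self, group_index: int) -> int | None:
        if group_index not in self.sides:
            raise KeyError(f"no crop entry for group {group_index}")
        return self.sides[group_index]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "base_side": self.base_side,
            "levels": self.levels,
            "sides": {str(k): v for k, v in sorted(self.sides.items())},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CropSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            sides={int(k): v for k, v in d["sides"].items()},
            base_side=d["base_side"],
            levels=d.get("levels", 4),
        )


def center_crop(image: np.ndarray, r: int) -> np.ndarray:
    """Copy the centered r x r window of an image (H x W or H x W x C).

    Raises if the window exceeds the frame; never pads or resamples.
    """
    if r < 1:
        raise ValueError("crop side must be >= 1")
    h, w = image.shape[:2]
    if r > min(h, w):
        raise ValueError(f"crop side {r} exceeds frame {h}x{w}")
    cy, cx = h // 2, w // 2
    y0 = cy - r // 2
    x0 = cx - r // 2
    return image[y0 : y0 + r, x0 : x0 + r].copy()


def apply_crop(image: np.ndarray, side: int | None) -> np.ndarray:
    """Identity for ``side=None`` (residual group), else a centered crop."""
    return image if side is None else center_crop(image, side)


def select_optimal_crop(
    group_index: int,
    candidates: Sequence[int],
    selector: str = "auto",
    *,
    manual_config: Mapping[int, int] | None = None,
    images: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
    val_images: np.ndarray | None = None,
    val_labels: Sequence[str] | None = None,
    input_side: int = 32,
    seed: int = 0,
) -> int:
    """Pick the window side for a similarity group.

    selector="manual": return the configured expert side for this group.
    selector="auto": crop the group's training/validation images to every
    candidate side, fit a quick multinomial-logistic proxy on downscaled
    pixels, and return the side with the best validation accuracy (ties ->
    larger side).  Per-candidate scores are logged.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate sides")
    if selector == "manual":
        if manual_config is None or group_index not in manual_config:
            raise KeyError(f"no manual crop entry for group {group_index}")
        side = int(manual_config[group_index])
        if side not in candidates:
            logger.warning(
                "manual side %d for group %d is not on the candidate ladder %s",
                side,
                group_index,
                candidates,
            )
        return side
    if selector != "auto":
        raise ValueError(f"unknown selector {selector!r}")
    if len(candidates) == 1:
        return candidates[0]
    if images is None or labels is None or val_images is None or val_labels is None:
        raise ValueError("auto selection needs train and validation images+labels")
    if len(set(labels)) < 2:
        raise ValueError("auto selection needs >=2 classes in the group")

    from .model import prepare_batch

    scores: dict[int, float] = {}
    for side in candidates:
        xtr = prepare_batch(np.stack([center_crop(im, side) for im in images]), input_side)
        xva = prepare_batch(
            np.stack([center_crop(im, side) for im in val_images]), input_side
        )
        scores[side] = _proxy_accuracy(
            xtr.reshape(len(xtr), -1),
            np.asarray(labels),
            xva.reshape(len(xva), -1),
            np.asarray(val_labels),
            seed=seed,
        )
    best = max(scores, key=lambda s: (scores[s], s))  # ties -> larger side
    logger.info(
        "auto ROI for group %d: scores %s -> side %d", group_index, scores, best
    )
    return best


def _proxy_accuracy(xtr, ytr, xva, yva, seed: int = 0) -> float:
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    # a rough ranking signal; full convergence is not needed
    clf = LogisticRegression(max_iter=200, C=1.0, random_state=seed)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(xtr, ytr)
    return float((clf.predict(xva) == yva).mean())
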