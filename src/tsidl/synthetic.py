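"""Synthetic packaged-medication image generator with planted lookalikes.

Emulates the capture protocol of the reference study — every class is
photographed from 9 camera directions (a 3 x 3 tilt/pitch grid of -20, 0,
+20 degrees) at 8 in-plane rotations of 45 degrees, i.e. 72 images per
class — without any photography: images are rendered.

Each *package type* contributes a silhouette shape and base colour shared by
all its classes.  Each class carries a "coarse appearance" (a few coloured
label blocks).  Classes inside a *planted similarity group* share one coarse
appearance and differ only in a small, low-contrast central imprint glyph —
the only within-group discriminative signal, mimicking lookalike drugs whose
packaging is identical and whose pill imprints differ.  Residual classes get
unique coarse appearances and are easy to tell apart.

Because the imprint occupies a tiny central window, downscaling a full frame
to the backbone input side nearly erases it, while a centred crop magnifies
it: the generated data make region-of-interest cropping provably useful by
construction.

Rendering is pixel-deterministic given the seed (per-entity generators are
derived from (seed, package, class, pose) tuples).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grouping import SDList, SGMap

logger = logging.getLogger(__name__)

__all__ = ["SynthParams", "SynthDataset", "generate_dataset", "planted_truth", "benchmark_params"]

# package-type vocabulary (coarse classes of the pharmacy catalogue)
PACKAGE_NAMES = (
    "amp", "bot", "ccb", "supp", "blister", "vial",
    "syringe", "syrup", "tube", "powder", "paperbox", "enema",
)

_TILT_ANGLES = (-20.0, 0.0, 20.0)
_DESK_COLOR = np.array([0.36, 0.42, 0.38], dtype=np.float32)


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    planted_groups maps a package index to a list of groups, each a list of
    within-package class indices sharing one coarse appearance.  Defaults
    reproduce the reference protocol counts: 9 directions x 8 rotations = 72
    images per class, split 40/10/22 into training/validation/testing.
    """

    n_packages: int = 3
    classes_per_package: int = 4
    planted_groups: Mapping[int, tuple[tuple[int, ...], ...]] = field(default_factory=dict)
    image_side: int = 256
    rotations: int = 8
    tilts: int = 9  # 3x3 grid of tilt/pitch in {-20, 0, +20} degrees
    imprint_side: int = 24
    imprint_contrast: float = 0.12
    noise_sd: float = 0.05
    split_counts: tuple[int, int, int] = (40, 10, 22)  # train/val/test per class
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "planted_groups",
            {
                int(p): tuple(tuple(int(c) for c in g) for g in groups)
                for p, groups in dict(self.planted_groups).items()
            },
        )
        if self.n_packages < 1 or self.classes_per_package < 1:
            raise ValueError("need at least one package and one class per package")
        if self.n_packages > len(PACKAGE_NAMES):
            raise ValueError(f"at most {len(PACKAGE_NAMES)} package types supported")
        if not (0 < self.imprint_contrast <= 1):
            raise ValueError("imprint_contrast must lie in (0, 1]")
        if self.imprint_side >= self.image_side / 4:
            raise ValueError(
                f"imprint side {self.imprint_side} must stay below a quarter of "
                f"the frame ({self.image_side}/4) so the crop pyramid can isolate it"
            )
        tr, va, te = self.split_counts
        if tr + va + te != self.images_per_class:
            raise ValueError(
                f"split counts {self.split_counts} must sum to images/class "
                f"({self.images_per_class})"
            )
        if (tr + va) % self.n_folds != 0 or va != (tr + va) // self.n_folds:
            raise ValueError(
                "validation count must be (train+val)/n_folds so folds rotate evenly"
            )
        for p, groups in self.planted_groups.items():
            if not (0 <= p < self.n_packages):
                raise ValueError(f"planted package index {p} out of range")
            seen: set[int] = set()
            for g in groups:
                if len(g) < 2:
                    raise ValueError(f"planted group {g} in package {p} has fewer than 2 classes")
                if any(not (0 <= c < self.classes_per_package) for c in g):
                    raise ValueError(f"planted class index out of range in {g}")
                if seen & set(g):
                    raise ValueError(f"planted groups overlap in package {p}")
                seen |= set(g)

    @property
    def images_per_class(self) -> int:
        return self.rotations * self.tilts

    @property
    def n_classes(self) -> int:
        return self.n_packages * self.classes_per_package

    def package_name(self, p: int) -> str:
        return PACKAGE_NAMES[p]

    def drug_label(self, p: int, c: int) -> str:
        return f"{self.package_name(p)}-{c:02d}"

    def class_list(self) -> list[tuple[str, str]]:
        """(drug label, package label) pairs in generation order."""
        return [
            (self.drug_label(p, c), self.package_name(p))
            for p in range(self.n_packages)
            for c in range(self.classes_per_package)
        ]

    def package_map(self):
        from .confmat import LabelMap

        return LabelMap({d: pkg for d, pkg in self.class_list()})


def benchmark_params(seed: int = 0) -> SynthParams:
    """The desk-scale planted benchmark: 3 packages x 4 classes, 2 planted
    similarity groups (sizes 3 and 2), 64-pixel frames, low imprint contrast."""
    return SynthParams(
        n_packages=3,
        classes_per_package=4,
        planted_groups={0: ((0, 1, 2),), 1: ((0, 1),)},
        image_side=64,
        imprint_side=10,
        imprint_contrast=0.12,
        noise_sd=0.06,
        seed=seed,
    )


@dataclass
class SynthDataset:
    """Rendered images (n, S, S, 3 float32 in [0,1]; None in count-only mode)
    plus the manifest inventory and the generating parameters."""

    images: np.ndarray | None
    manifest: pd.DataFrame
    params: SynthParams

    def images_for(self, paths: Sequence[str]) -> np.ndarray:
        if self.images is None:
            raise ValueError("dataset was generated in count-only mode (no pixels)")
        index = {p: i for i, p in enumerate(self.manifest["path"])}
        return self.images[[index[p] for p in paths]]


# ---------------------------------------------------------------------------
# rendering primitives


def _silhouette(shape_id: int, s: int) -> np.ndarray:
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    cy = cx = (s - 1) / 2
    u, v = (yy - cy) / s, (xx - cx) / s
    kind = shape_id % 5
    if kind == 0:  # circle
        return (u**2 + v**2) < 0.40**2
    if kind == 1:  # rounded square
        return (np.maximum(np.abs(u), np.abs(v)) < 0.38) & ((u**2 + v**2) < 0.52**2)
    if kind == 2:  # tall rectangle
        return (np.abs(u) < 0.44) & (np.abs(v) < 0.28)
    if kind == 3:  # wide rectangle
        return (np.abs(u) < 0.28) & (np.abs(v) < 0.44)
    return (np.abs(u) + np.abs(v)) < 0.52  # diamond


def _render_base(params: SynthParams, p: int, c: int) -> np.ndarray:
    """Pose-free canvas: desk pad + package silhouette + coarse appearance
    (shared within a planted group) + the class-unique central imprint."""
    s = params.image_side
    img = np.ones((s, s, 3), dtype=np.float32) * _DESK_COLOR

    pkg_rng = np.random.default_rng([params.seed, 101, p])
    mask = _silhouette(p, s)
    base_color = pkg_rng.uniform(0.35, 0.85, size=3).astype(np.float32)
    img[mask] = base_color

    # appearance unit: the planted group id, or the class itself when unplanted
    group_of = {c0: gi for gi, g in enumerate(params.planted_groups.get(p, ())) for c0 in g}
    if c in group_of:
        unit_rng = np.random.default_rng([params.seed, 202, p, 1, group_of[c]])
    else:
        unit_rng = np.random.default_rng([params.seed, 202, p, 2, c])
    for _ in range(3):  # coloured label blocks
        bh = int(unit_rng.integers(s // 8, s // 4))
        bw = int(unit_rng.integers(s // 8, s // 4))
        y0 = int(unit_rng.integers(s // 6, s - s // 6 - bh))
        x0 = int(unit_rng.integers(s // 6, s - s // 6 - bw))
        color = unit_rng.uniform(0.05, 0.95, size=3).astype(np.float32)
        block = np.zeros((s, s), dtype=bool)
        block[y0 : y0 + bh, x0 : x0 + bw] = True
        img[block & mask] = color

    # class-unique central imprint glyph at low contrast
    glyph_rng = np.random.default_rng([params.seed, 303, p, c])
    cells = glyph_rng.integers(0, 2, size=(5, 5)).astype(np.float32)
    side = params.imprint_side
    glyph = np.kron(cells, np.ones((side // 5 + 1, side // 5 + 1), np.float32))[:side, :side]
    y0 = x0 = s // 2 - side // 2
    img[y0 : y0 + side, x0 : x0 + side] -= params.imprint_contrast * glyph[..., None]
    return np.clip(img, 0.0, 1.0)


def _pose_transform(params: SynthParams, pose: int, s: int):
    """Affine warp for pose = tilt_index * rotations + rotation_index."""
    from skimage.transform import AffineTransform

    tilt_idx, rot_idx = divmod(pose, params.rotations)
    if params.tilts == 9:
        ty = _TILT_ANGLES[tilt_idx // 3]
        tx = _TILT_ANGLES[tilt_idx % 3]
    else:  # evenly spread tilts on one axis for non-default grids
        ty = _TILT_ANGLES[tilt_idx % 3]
        tx = 0.0
    rot = np.deg2rad(rot_idx * (360.0 / params.rotations))
    # camera tilt foreshortens each axis by cos(angle) and shifts slightly
    sy, sx = np.cos(np.deg2rad(ty)), np.cos(np.deg2rad(tx))
    shift_y = np.sin(np.deg2rad(ty)) * 0.03 * s
    shift_x = np.sin(np.deg2rad(tx)) * 0.03 * s
    center = (s - 1) / 2
    to_origin = AffineTransform(translation=(-center, -center))
    motion = AffineTransform(rotation=rot, scale=(sx, sy))
    back = AffineTransform(translation=(center + shift_x, center + shift_y))
    return to_origin + motion + back


def _render_pose(params: SynthParams, base: np.ndarray, p: int, c: int, pose: int) -> np.ndarray:
    from skimage.transform import warp

    s = params.image_side
    tform = _pose_transform(params, pose, s)
    img = warp(base, tform.inverse, order=1, mode="edge", preserve_range=True).astype(np.float32)
    jitter_rng = np.random.default_rng([params.seed, 404, p, c, pose])
    img = img * (1.0 + 0.08 * jitter_rng.uniform(-1.0, 1.0))  # illumination
    img = img + jitter_rng.normal(0.0, params.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# public API


def generate_dataset(
    params: SynthParams,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> SynthDataset:
    """Render the dataset (or only its manifest when ``render=False``).

    Every class gets rotations x tilts images.  Per class, a seeded
    permutation assigns train+val images to 5 rotating folds (the fold
    column marks which fold uses the image for validation) and the remainder
    to the fixed test block.  With ``out_dir`` set, images are written as
    PNG, the manifest as TSV, and the parameters as a JSON sidecar.
    """
    tr, va, te = params.split_counts
    n_img = params.images_per_class
    rows: list[dict] = []
    images: list[np.ndarray] = []
    for p in range(params.n_packages):
        for c in range(params.classes_per_package):
            drug = params.drug_label(p, c)
            split_rng = np.random.default_rng([params.seed, 505, p, c])
            order = split_rng.permutation(n_img)
            fold_of = np.zeros(n_img, dtype=int)  # 0 = test block
            for f in range(params.n_folds):
                fold_of[order[f * va : (f + 1) * va]] = f + 1
            base = _render_base(params, p, c) if render else None
            for pose in range(n_img):
                rows.append(
                    {
                        "path": f"images/{drug}/pose{pose:02d}.png",
                        "drug": drug,
                        "package": params.package_name(p),
                        "split": "trainval" if fold_of[pose] > 0 else "test",
                        "fold": int(fold_of[pose]),
                        "pose": pose,
                    }
                )
                if render:
                    images.append(_render_pose(params, base, p, c, pose))
    manifest = pd.DataFrame(rows)
    stack = np.stack(images) if render else None
    ds = SynthDataset(images=stack, manifest=manifest, params=params)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SynthDataset, out_dir: Path) -> None:
    from PIL import Image

    out_dir.mkdir(parents=True, exist_ok=True)
    if ds.images is not None:
        for row, img in zip(ds.manifest.itertuples(), ds.images):
            path = out_dir / row.path
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((img * 255).round().astype(np.uint8)).save(path)
    ds.manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    payload = asdict(ds.params)
    payload["planted_groups"] = {
        str(k): [list(g) for g in v] for k, v in ds.params.planted_groups.items()
    }
    (out_dir / "synth_params.json").write_text(json.dumps(payload, indent=2))


def planted_truth(params: SynthParams) -> SGMap:
    """Ground-truth SG map: the planted groups as SD lists, rest residual."""
    groups: list[SDList] = []
    grouped: set[str] = set()
    for p in sorted(params.planted_groups):
        for g in params.planted_groups[p]:
            members = frozenset(params.drug_label(p, c) for c in g)
            groups.append(SDList(params.package_name(p), members))
            grouped |= members
    groups.sort(key=lambda g: (g.package_class, sorted(g.members)[0]))
    residual = frozenset(d for d, _ in params.class_list()) - grouped
    return SGMap(tuple(groups), residual, provenance={"source": "planted"})
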