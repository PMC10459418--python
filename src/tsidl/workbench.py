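"""Shared plumbing: run configuration, manifest reader/writer, report rendering.

Artifacts follow one convention throughout: TSV for tables (manifest,
confusion matrices), JSON for structured objects (SG map, crop spec, metric
reports, checkpoints metadata), YAML for run configuration.  Every run
directory carries the seed and a digest of the configuration that produced
it, so a run is reproducible from (config, seed, manifest) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .confmat import ConfusionMatrix, MetricsReport
from .grouping import GroupingParams, SGMap
from .model import TrainConfig
from .roi import CropSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_manifest", "write_manifest", "load_images", "render_report"]

MANIFEST_COLUMNS = ("path", "drug", "package", "split", "fold", "pose")


@dataclass
class RunConfig:
    """Every knob of a full run, with defaults, loadable from YAML."""

    seed: int = 0
    backbone: str = "tiny"  # tiny | sscnn
    input_side: int = 32
    train: TrainConfig = field(default_factory=TrainConfig)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    crop_levels: int = 4
    crop_selector: str = "auto"  # auto | manual
    manual_crops: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        train = TrainConfig(**raw.pop("train", {}))
        grouping = GroupingParams(**raw.pop("grouping", {}))
        manual = {int(k): int(v) for k, v in raw.pop("manual_crops", {}).items()}
        return cls(train=train, grouping=grouping, manual_crops=manual, **raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset manifest TSV.

    Enforces the required header, unique image paths, and a consistent
    drug -> package assignment (a drug listed under two packages is a
    labelling error upstream and is rejected).
    """
    m = pd.read_csv(path, sep="\t", dtype={"path": str, "drug": str, "package": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in m.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    dup = m["path"][m["path"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate manifest paths: {sorted(set(dup))[:5]}")
    pkgs = m.groupby("drug")["package"].nunique()
    bad = pkgs[pkgs > 1]
    if not bad.empty:
        raise ValueError(
            f"drugs mapped to multiple packages: {sorted(bad.index)}"
        )
    bad_split = set(m["split"]) - {"trainval", "test"}
    if bad_split:
        raise ValueError(f"unknown split values: {sorted(bad_split)}")
    return m


def write_manifest(m: pd.DataFrame, path: str | Path) -> None:
    m.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, sep="\t", index=False)


def load_images(manifest: pd.DataFrame, root: str | Path) -> np.ndarray:
    """Load manifest images (PNG) into an (n, H, W, 3) float32 stack in [0,1]."""
    from PIL import Image

    root = Path(root)
    stack = []
    for p in manifest["path"]:
        with Image.open(root / p) as im:
            stack.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
    return np.stack(stack)


def render_report(run_dir: str | Path) -> str:
    """Deterministic plain-text summary of a completed run directory.

    Expects the artifacts a full run writes: validation/testing CVCM TSVs,
    sg_map.json, crop_spec.json, and metrics_<level>.json files.  Raises
    listing whatever is missing.
    """
    d = Path(run_dir)
    required = ["val_cvcm.tsv", "test_cvcm.tsv", "sg_map.json", "crop_spec.json"]
    metric_files = sorted(d.glob("metrics_*.json"))
    missing = [f for f in required if not (d / f).exists()]
    if not metric_files:
        missing.append("metrics_<level>.json")
    if missing:
        raise FileNotFoundError(f"incomplete run {d}: missing {missing}")

    sg = SGMap.from_json(d / "sg_map.json")
    crops = CropSpec.from_json(d / "crop_spec.json")
    val_cvcm = ConfusionMatrix.from_tsv(d / "val_cvcm.tsv")
    lines = [f"run summary: {d.name}", "=" * 40, ""]
    lines.append(f"classes: {val_cvcm.r}; validation CVCM total: {val_cvcm.total}")
    lines.append("")
    lines.append(f"similarity groups ({sg.n_groups} + residual):")
    for k, g in enumerate(sg.groups, start=1):
        lines.append(
            f"  SG{k} [{g.package_class}] crop={crops.side_for(k)}: "
            + ", ".join(sorted(g.members))
        )
    lines.append(
        f"  SG{sg.residual_index} [residual] crop=full frame: {len(sg.residual)} classes"
    )
    lines.append("")
    for f in metric_files:
        rep = MetricsReport.from_json(f)
        level = f.stem.replace("metrics_", "")
        lines.append(
            f"{level:>8}-level  acc={rep.accuracy:.4f}  "
            f"macroR={rep.macro_recall:.4f}  macroP={rep.macro_precision:.4f}  "
            f"macroF1={rep.macro_f1:.4f}"
        )
    lines.append("")
    lines.append("top validation confusions:")
    cm = val_cvcm.counts.copy()
    np.fill_diagonal(cm, 0)
    flat = np.argsort(cm, axis=None)[::-1][:5]
    for idx in flat:
        i, j = np.unravel_index(idx, cm.shape)
        if cm[i, j] == 0:
            break
        lines.append(f"  {val_cvcm.labels[i]} -> {val_cvcm.labels[j]}: {cm[i, j]}")
    return "\n".join(lines) + "\n"
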