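"""Two-stage induced deep learning: orchestration of the full method.

Stage 1 trains a global classifier over every class and evaluates it by
5-fold cross-validation over the 50-image train+val pool of each class (per
fold: 40 training, 10 validation images; the 22-image test block per class
never enters CV).  The five per-fold confusion matrices are summed into
cross-validated confusion matrices (CVCMs): the *validation* CVCM (support
50 per class) feeds the similar-class grouping; the *testing* CVCM (support
5 x 22 = 110 per class) is diagnostic.

The grouping step turns the validation CVCM into a similarity-group (SG)
map.  For each similarity group an optimal centred crop side is chosen from
the halving pyramid, and a dedicated stage-2 classifier is trained on the
cropped images of that group's classes only (the residual group keeps full
frames).  Deployment inference routes each image through a final stage-1
model trained on the whole pool, looks its predicted class up in the SG map,
applies the group's crop, and lets the group's stage-2 model decide.  A
stage-1 routing error is irrecoverable by construction: stage 2 can only
answer within the routed group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .confmat import (
    ConfusionMatrix,
    LabelMap,
    MetricsReport,
    aggregate_folds,
    build_cm,
    macro_metrics,
    project,
)
from .grouping import GroupingParams, SGMap, assign_group, find_similar_groups
from .model import (
    ArchitectureSpec,
    TrainConfig,
    TrainedModel,
    predict,
    prepare_batch,
    tiny_spec,
    train,
)
from .roi import CropSpec, center_crop, pyramid_sizes, select_optimal_crop
from .synthetic import SynthDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "StageOneResult",
    "TsidlBundle",
    "desk_train_config",
    "run_stage1",
    "train_final_stage1",
    "build_sg_map",
    "select_crops",
    "train_stage2",
    "fit_tsidl",
    "infer_two_stage",
    "evaluate",
    "evaluate_single_stage",
]


def _subseed(seed: int, *tags: int) -> int:
    """Derive a reproducible child seed (< 2**31) from a root seed and tags."""
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def desk_train_config(seed: int = 0) -> TrainConfig:
    """Optimization settings for the tiny desk-scale backbone.

    The reference settings (learning rate 1e-4, batch 32, 100 epochs) are
    tuned to a pretrained AlexNet-scale network; the tiny backbone trains
    from scratch, so it uses a larger rate and fewer epochs.
    """
    return TrainConfig(learning_rate=0.02, batch_size=32, max_epochs=45, seed=seed)


@dataclass(frozen=True)
class FoldPlan:
    """Per-class rotation of the train+val pool into n_folds validation blocks.

    fold_of maps image path -> fold index (1..n_folds) whose validation
    block contains the image; test paths are absent.
    """

    n_folds: int
    fold_of: Mapping[str, int]

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame, n_folds: int = 5) -> "FoldPlan":
        tv = manifest[manifest["split"] == "trainval"]
        if tv.empty:
            raise ValueError("manifest has no trainval rows")
        folds = set(tv["fold"])
        if folds != set(range(1, n_folds + 1)):
            raise ValueError(
                f"trainval folds {sorted(folds)} do not cover 1..{n_folds}"
            )
        per_class = tv.groupby(["drug", "fold"]).size().unstack(fill_value=0)
        if per_class.to_numpy().std() != 0:
            logger.warning("fold blocks are not perfectly balanced across classes")
        return cls(n_folds, dict(zip(tv["path"], tv["fold"])))


@dataclass
class StageOneResult:
    """Five fold-models plus their aggregated validation and testing CVCMs."""

    fold_models: list[TrainedModel]
    val_cvcm: ConfusionMatrix
    test_cvcm: ConfusionMatrix
    labels: tuple[str, ...]


@dataclass
class TsidlBundle:
    """Everything deployment inference needs."""

    model0: TrainedModel
    sg_map: SGMap
    crop_spec: CropSpec
    stage2_models: Mapping[int, TrainedModel]

    def __post_init__(self) -> None:
        for k in range(1, self.sg_map.n_groups + 1):
            if k not in self.stage2_models:
                raise ValueError(f"no stage-2 model for similarity group {k}")
            have = set(self.stage2_models[k].labels)
            want = set(self.sg_map.members_of(k))
            if have != want:
                raise ValueError(
                    f"stage-2 model {k} covers {sorted(have)} but the group is {sorted(want)}"
                )
        ridx = self.sg_map.residual_index
        if ridx in self.stage2_models:
            have = set(self.stage2_models[ridx].labels)
            if have != set(self.sg_map.residual):
                raise ValueError("residual model labels do not match the residual group")


# ---------------------------------------------------------------------------
# stage 1


def _check_dataset(dataset: SynthDataset) -> pd.DataFrame:
    m = dataset.manifest
    for col in ("path", "drug", "package", "split", "fold"):
        if col not in m.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    missing = set(m["drug"]) - set(m[m["split"] == "test"]["drug"])
    if missing:
        raise ValueError(f"classes without a test block: {sorted(missing)}")
    missing = set(m["drug"]) - set(m[m["split"] == "trainval"]["drug"])
    if missing:
        raise ValueError(f"classes without trainval images: {sorted(missing)}")
    return m


def run_stage1(
    dataset: SynthDataset,
    spec_fn: Callable[[int], ArchitectureSpec] = tiny_spec,
    config: TrainConfig | None = None,
    n_folds: int = 5,
) -> StageOneResult:
    """5-fold cross-validation of the global stage-1 classifier.

    Each fold trains on the other folds' blocks and validates on its own
    block; every fold-model is additionally evaluated on the same fixed test
    split.  Per-fold confusion matrices are summed into the validation and
    testing CVCMs.
    """
    m = _check_dataset(dataset)
    config = config or desk_train_config()
    plan = FoldPlan.from_manifest(m, n_folds)
    labels = tuple(sorted(m["drug"].unique()))
    spec = spec_fn(len(labels))

    tv = m[m["split"] == "trainval"]
    test = m[m["split"] == "test"]
    test_images = dataset.images_for(list(test["path"]))
    test_prepared = prepare_batch(test_images, spec.input_side)

    val_cms, test_cms, fold_models = [], [], []
    for f in range(1, n_folds + 1):
        va = tv[tv["fold"] == f]
        tr = tv[tv["fold"] != f]
        model = train(
            dataset.images_for(list(tr["path"])),
            list(tr["drug"]),
            dataset.images_for(list(va["path"])),
            list(va["drug"]),
            spec,
            config.with_seed(_subseed(config.seed, 1, f)),
        )
        fold_models.append(model)
        val_pred, _ = predict(model, prepare_batch(dataset.images_for(list(va["path"])), spec.input_side).transpose(0, 2, 3, 1))
        val_cms.append(build_cm(list(va["drug"]), val_pred, labels))
        test_pred, _ = predict(model, test_prepared.transpose(0, 2, 3, 1))
        test_cms.append(build_cm(list(test["drug"]), test_pred, labels))
        logger.info(
            "fold %d/%d: val acc %.3f, test acc %.3f",
            f,
            n_folds,
            np.diag(val_cms[-1].counts).sum() / val_cms[-1].total,
            np.diag(test_cms[-1].counts).sum() / test_cms[-1].total,
        )
    return StageOneResult(
        fold_models=fold_models,
        val_cvcm=aggregate_folds(val_cms),
        test_cvcm=aggregate_folds(test_cms),
        labels=labels,
    )


def _resplit_trainval(
    m: pd.DataFrame, seed: int, val_fraction: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded per-class re-split of the trainval pool (default 40/10 of 50)."""
    import zlib

    tv = m[m["split"] == "trainval"]
    val_paths: list[str] = []
    for drug, grp in tv.groupby("drug"):
        rng = np.random.default_rng([seed, zlib.crc32(str(drug).encode())])
        n_val = max(1, int(round(len(grp) * val_fraction)))
        val_paths.extend(rng.choice(grp["path"].to_numpy(), size=n_val, replace=False))
    val_set = set(val_paths)
    return tv[~tv["path"].isin(val_set)], tv[tv["path"].isin(val_set)]


def train_final_stage1(
    dataset: SynthDataset,
    spec_fn: Callable[[int], ArchitectureSpec] = tiny_spec,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """The deployment stage-1 model, trained on a seeded 40/10 re-split of
    the full train+val pool (the five fold-models exist only for the CVCMs)."""
    m = _check_dataset(dataset)
    config = config or desk_train_config()
    labels = tuple(sorted(m["drug"].unique()))
    spec = spec_fn(len(labels))
    tr, va = _resplit_trainval(m, _subseed(config.seed, 2))
    return train(
        dataset.images_for(list(tr["path"])),
        list(tr["drug"]),
        dataset.images_for(list(va["path"])),
        list(va["drug"]),
        spec,
        config.with_seed(_subseed(config.seed, 3)),
    )


# ---------------------------------------------------------------------------
# grouping + ROI selection


def build_sg_map(
    stage1: StageOneResult,
    package_of: Mapping[str, str],
    params: GroupingParams = GroupingParams(),
) -> SGMap:
    """Similarity groups from the VALIDATION CVCM (never the testing CVCM)."""
    sg = find_similar_groups(stage1.val_cvcm, package_of, params)
    prov = dict(sg.provenance)
    prov["source"] = "stage1-validation-cvcm"
    return SGMap(sg.groups, sg.residual, prov)


def select_crops(
    dataset: SynthDataset,
    sg_map: SGMap,
    levels: int = 4,
    selector: str = "auto",
    manual_config: Mapping[int, int] | None = None,
    input_side: int = 32,
    seed: int = 0,
) -> CropSpec:
    """Choose a crop side per similarity group from the halving pyramid.

    The residual group always keeps the full frame (identity).  The auto
    selector scores candidates on the group's own trainval images using the
    seeded fold-1 block for validation.
    """
    m = dataset.manifest
    base = dataset.params.image_side
    candidates = pyramid_sizes(base, levels)
    sides: dict[int, int | None] = {sg_map.residual_index: None}
    for k in range(1, sg_map.n_groups + 1):
        members = sg_map.members_of(k)
        tv = m[(m["split"] == "trainval") & m["drug"].isin(members)]
        tr = tv[tv["fold"] != 1]
        va = tv[tv["fold"] == 1]
        sides[k] = select_optimal_crop(
            k,
            candidates,
            selector=selector,
            manual_config=manual_config,
            images=dataset.images_for(list(tr["path"])),
            labels=list(tr["drug"]),
            val_images=dataset.images_for(list(va["path"])),
            val_labels=list(va["drug"]),
            input_side=input_side,
            seed=_subseed(seed, 4, k),
        )
    return CropSpec(sides=sides, base_side=base, levels=levels)


# ---------------------------------------------------------------------------
# stage 2


def _crop_stack(images: np.ndarray, side: int | None) -> np.ndarray:
    if side is None:
        return images
    return np.stack([center_crop(im, side) for im in images])


def train_stage2(
    dataset: SynthDataset,
    sg_map: SGMap,
    crop_spec: CropSpec,
    spec_fn: Callable[[int], ArchitectureSpec] = tiny_spec,
    config: TrainConfig | None = None,
    overrides: Mapping[int, TrainConfig] | None = None,
) -> dict[int, TrainedModel]:
    """One dedicated classifier per similarity group plus the residual.

    Each group's trainval images are cropped to the group's chosen side
    (residual: full frame) and a model over exactly that group's labels is
    trained on a seeded 40/10-style re-split.
    """
    m = _check_dataset(dataset)
    config = config or desk_train_config()
    models: dict[int, TrainedModel] = {}
    indices = list(range(1, sg_map.n_groups + 1)) + [sg_map.residual_index]
    for k in indices:
        members = sg_map.members_of(k)
        if len(members) < 2:
            raise ValueError(
                f"group {k} has {len(members)} class(es); a classifier needs >= 2"
            )
        side = crop_spec.side_for(k)
        sub = m[m["drug"].isin(members)]
        tr, va = _resplit_trainval(sub, _subseed(config.seed, 5, k))
        cfg = (overrides or {}).get(k, config)
        models[k] = train(
            _crop_stack(dataset.images_for(list(tr["path"])), side),
            list(tr["drug"]),
            _crop_stack(dataset.images_for(list(va["path"])), side),
            list(va["drug"]),
            spec_fn(len(members)),
            cfg.with_seed(_subseed(cfg.seed, 6, k)),
        )
        logger.info(
            "stage-2 model %d (%d classes, crop %s): best val acc %.3f",
            k,
            len(members),
            side,
            max(models[k].history["val_accuracy"]),
        )
    return models


def fit_tsidl(
    dataset: SynthDataset,
    spec_fn: Callable[[int], ArchitectureSpec] = tiny_spec,
    config: TrainConfig | None = None,
    grouping_params: GroupingParams = GroupingParams(),
    crop_selector: str = "auto",
    manual_crops: Mapping[int, int] | None = None,
) -> tuple[TsidlBundle, StageOneResult]:
    """End-to-end training: stage-1 CV -> grouping -> crops -> stage 2."""
    config = config or desk_train_config()
    stage1 = run_stage1(dataset, spec_fn, config)
    sg_map = build_sg_map(stage1, dataset.params.package_map(), grouping_params)
    input_side = spec_fn(2).input_side
    crop_spec = select_crops(
        dataset,
        sg_map,
        selector=crop_selector,
        manual_config=manual_crops,
        input_side=input_side,
        seed=config.seed,
    )
    model0 = train_final_stage1(dataset, spec_fn, config)
    stage2 = train_stage2(dataset, sg_map, crop_spec, spec_fn, config)
    return TsidlBundle(model0, sg_map, crop_spec, stage2), stage1


# ---------------------------------------------------------------------------
# inference + evaluation


@dataclass
class InferenceRecord:
    """Audit trail of one two-stage prediction."""

    stage1_label: str
    group_index: int
    final_label: str
    stage1_scores: np.ndarray = field(repr=False, default=None)
    stage2_scores: np.ndarray = field(repr=False, default=None)


def infer_two_stage(images: np.ndarray, bundle: TsidlBundle) -> list[InferenceRecord]:
    """Route every image: stage-1 label -> group -> crop -> stage-2 label.

    The final label always belongs to the routed group's label set; images
    routed to the residual get the identity crop.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    side0 = bundle.model0.input_side
    s1_labels, s1_scores = predict(
        bundle.model0, prepare_batch(images, side0).transpose(0, 2, 3, 1)
    )
    records: list[InferenceRecord | None] = [None] * len(images)
    by_group: dict[int, list[int]] = {}
    for i, lab in enumerate(s1_labels):
        by_group.setdefault(assign_group(lab, bundle.sg_map), []).append(i)
    for k, idxs in by_group.items():
        model = bundle.stage2_models[k]
        cropped = _crop_stack(images[idxs], bundle.crop_spec.side_for(k))
        final, s2_scores = predict(
            model, prepare_batch(cropped, model.input_side).transpose(0, 2, 3, 1)
        )
        for j, i in enumerate(idxs):
            records[i] = InferenceRecord(
                stage1_label=s1_labels[i],
                group_index=k,
                final_label=final[j],
                stage1_scores=s1_scores[i],
                stage2_scores=s2_scores[j],
            )
    return records  # type: ignore[return-value]


def _group_map(sg_map: SGMap) -> LabelMap:
    return LabelMap({lab: f"SG{assign_group(lab, sg_map)}" for lab in sg_map.all_labels()})


def evaluate(
    bundle: TsidlBundle,
    dataset: SynthDataset,
    package_of: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """Two-stage metrics on the test split at drug, package and group level."""
    m = _check_dataset(dataset)
    test = m[m["split"] == "test"]
    if test.empty:
        raise ValueError("empty test split")
    package_of = package_of or dataset.params.package_map()
    records = infer_two_stage(dataset.images_for(list(test["path"])), bundle)
    preds = [r.final_label for r in records]
    return _leveled_metrics(list(test["drug"]), preds, bundle.sg_map, package_of)


def evaluate_single_stage(
    model0: TrainedModel,
    dataset: SynthDataset,
    sg_map: SGMap,
    package_of: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """Stage-1-only metrics on the test split (the baseline TSIDL must beat)."""
    m = _check_dataset(dataset)
    test = m[m["split"] == "test"]
    package_of = package_of or dataset.params.package_map()
    images = dataset.images_for(list(test["path"]))
    preds, _ = predict(
        model0, prepare_batch(images, model0.input_side).transpose(0, 2, 3, 1)
    )
    return _leveled_metrics(list(test["drug"]), preds, sg_map, package_of)


def _leveled_metrics(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    sg_map: SGMap,
    package_of: Mapping[str, str],
) -> dict[str, dict]:
    labels = tuple(sorted(set(true_labels) | set(pred_labels)))
    fine = build_cm(true_labels, pred_labels, labels)
    pkg = project(fine, LabelMap(dict(package_of)))
    grp = project(fine, _group_map(sg_map))
    return {
        "drug": {"cm": fine, "metrics": macro_metrics(fine)},
        "package": {"cm": pkg, "metrics": macro_metrics(pkg)},
        "group": {"cm": grp, "metrics": macro_metrics(grp)},
    }
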