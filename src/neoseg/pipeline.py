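"""End-to-end reproducible pipeline: phantoms -> training -> evaluation.

``run_pipeline`` chains the stages — simulate, preprocess, split, train,
segment, evaluate — writing every intermediate artifact below one output
root, and is a pure function of ``(RunConfig, master seed)``.  Stage
seeds derive from the master seed by fixed offsets so a stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .metrics import (
    ConfusionCounts,
    EvaluationReport,
    aggregate_report,
    compute_metrics,
    confusion,
    patch_classify,
    segment_probabilities,
)
from .nn.model import SegmentationNetwork
from .phantom import PhantomConfig, emit_dataset, render_phantom
from .preprocess import (
    PatchGrid,
    apply_clahe,
    augment_flips,
    extract_green,
    normalize_patch,
    split_dataset,
    split_patches,
)
from .train import TrainingConfig, train

__all__ = ["RunConfig", "StageError", "run_pipeline", "make_fixtures", "preprocess_image"]

# Fixed seed offsets per stage (stage seed = master seed + offset).
SEED_OFFSETS = {"simulate": 0, "split": 1009, "init": 2003, "train": 3001}


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs, serializable to YAML."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_images: int = 6
    clip_limit: float = 0.01
    clahe_tile_rows: int = 8
    clahe_tile_cols: int = 8
    patch_height: int = 80
    patch_width: int = 296
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    eval_tile_height: int = 40
    eval_tile_width: int = 74
    master_seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["phantom"]["lesion_radius_range"] = list(self.phantom.lesion_radius_range)
        d["training"]["class_weights"] = list(self.training.class_weights)
        d["fractions"] = list(self.fractions)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        ph = d.pop("phantom", {})
        ph["lesion_radius_range"] = tuple(ph.get("lesion_radius_range", (12.0, 28.0)))
        tr = d.pop("training", {})
        tr["class_weights"] = tuple(tr.get("class_weights", (1.0, 1.0)))
        d["fractions"] = tuple(d.get("fractions", (0.5, 0.25, 0.25)))
        return cls(phantom=PhantomConfig(**ph), training=TrainingConfig(**tr), **d)


def preprocess_image(
    rgb: np.ndarray,
    mask: np.ndarray,
    config: RunConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Enhancement chain for one image: green -> CLAHE -> patch -> normalize.

    The mask follows only the geometric patching; contrast operations
    never touch labels.
    """
    gray = extract_green(rgb)
    gray = apply_clahe(
        gray, config.clip_limit, config.clahe_tile_rows, config.clahe_tile_cols
    )
    grid = PatchGrid(config.patch_height, config.patch_width, mode="exact")
    patches = [normalize_patch(p) for p in split_patches(gray, grid)]
    mask_patches = split_patches(np.asarray(mask), grid)
    return patches, mask_patches


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-labeled and re-raised
                raise StageError(f"stage={name}: {exc}") from exc

        return run

    return wrap


def run_pipeline(config: RunConfig, out_dir: str | Path, log=print) -> EvaluationReport:
    """Execute the full pipeline under ``out_dir``; returns the report.

    Artifacts: ``phantoms/`` (PNG pairs + manifest), ``split.tsv``,
    ``history.csv``, ``checkpoint.npz``, ``predictions/`` (PNG masks) and
    ``report.csv``.  Idempotent under a fixed config and master seed;
    partial outputs are retained when a stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed

    @_stage("simulate")
    def simulate():
        cfg = dataclasses.replace(config.phantom, seed=seed + SEED_OFFSETS["simulate"])
        manifest = emit_dataset(cfg, config.n_images, out / "phantoms")
        log(f"stage=simulate n_images={config.n_images}")
        images, masks = [], []
        for img_name, mask_name, _ in manifest:
            images.append(np.asarray(Image.open(out / "phantoms" / img_name)))
            masks.append(np.asarray(Image.open(out / "phantoms" / mask_name)))
        return images, masks

    images, masks = simulate()

    @_stage("preprocess")
    def preprocess():
        patches, mask_patches = [], []
        for rgb, mask in zip(images, masks):
            p, m = preprocess_image(rgb, mask, config)
            patches.extend(p)
            mask_patches.extend(m)
        log(f"stage=preprocess n_patches={len(patches)}")
        return patches, mask_patches

    patches, mask_patches = preprocess()

    @_stage("split")
    def split():
        ds = split_dataset(len(patches), config.fractions, seed=seed + SEED_OFFSETS["split"])
        with open(out / "split.tsv", "w") as fh:
            fh.write("patch_index\tsubset\n")
            for subset in ("train", "validation", "test"):
                for i in getattr(ds, subset):
                    fh.write(f"{i}\t{subset}\n")
        log(
            f"stage=split train={len(ds.train)} validation={len(ds.validation)} "
            f"test={len(ds.test)}"
        )
        return ds

    ds = split()

    @_stage("train")
    def train_stage():
        tr_p, tr_m = augment_flips(
            [patches[i] for i in ds.train], [mask_patches[i] for i in ds.train]
        )
        model = SegmentationNetwork.reference(
            config.patch_height, config.patch_width, seed=seed + SEED_OFFSETS["init"]
        )
        tcfg = dataclasses.replace(config.training, seed=seed + SEED_OFFSETS["train"])
        model, history = train(
            model,
            tr_p,
            tr_m,
            [patches[i] for i in ds.validation],
            [mask_patches[i] for i in ds.validation],
            tcfg,
            log=log,
        )
        (out / "history.csv").write_text(history.to_csv())
        model.save(out / "checkpoint.npz")
        log(
            f"stage=train iterations={len(history.train_loss)} "
            f"stop_reason={history.stop_reason} best_iteration={history.best_iteration}"
        )
        return model

    model = train_stage()

    @_stage("segment")
    def segment_stage():
        pred_dir = out / "predictions"
        pred_dir.mkdir(exist_ok=True)
        preds = []
        for k, i in enumerate(ds.test):
            probs = model.predict_proba(patches[i])[0]
            pred = segment_probabilities(probs)
            Image.fromarray(pred).save(pred_dir / f"test_{k:03d}_pred.png")
            Image.fromarray((mask_patches[i] > 0).astype(np.uint8) * 255).save(
                pred_dir / f"test_{k:03d}_truth.png"
            )
            preds.append(pred)
        log(f"stage=segment n_test={len(preds)}")
        return preds

    preds = segment_stage()

    @_stage("evaluate")
    def evaluate_stage():
        records = []
        pooled = ConfusionCounts(0, 0, 0, 0)
        for pred, i in zip(preds, ds.test):
            truth = mask_patches[i]
            records.append(compute_metrics(confusion(pred, truth)))
            pooled = pooled + patch_classify(
                pred, truth, config.eval_tile_height, config.eval_tile_width
            )
        report = aggregate_report(records, patch_counts=pooled)
        (out / "report.csv").write_text(report.to_csv())
        log(f"stage=evaluate n_records={len(records)}")
        return report

    return evaluate_stage()


def make_fixtures(seed: int = 20240) -> list[dict]:
    """Deterministic 6-phantom toy set with oracle confusion counts.

    Each entry carries the rendered image, the ground-truth mask, a
    synthetic "prediction" (the truth translated by one pixel, so every
    count class is populated) and the expected confusion counts computed
    by an explicit per-pixel loop, independent of the vectorized tally.
    """
    fixtures = []
    for i in range(6):
        cfg = PhantomConfig(
            image_height=160,
            image_width=160,
            n_lesions=1 + i % 2,
            vessel_branching_depth=3,
            lesion_radius_range=(8.0, 14.0),
            lesion_vessel_count=6,
            noise_sd=2.0,
            seed=seed + i,
        )
        image, mask = render_phantom(cfg)
        pred = np.roll(mask.labels, shift=1, axis=1)  # translated truth
        tp = tn = fp = fn = 0
        for r in range(mask.height):
            for c in range(mask.width):
                p, t = pred[r, c] > 0, mask.labels[r, c] > 0
                if p and t:
                    tp += 1
                elif p and not t:
                    fp += 1
                elif not p and t:
                    fn += 1
                else:
                    tn += 1
        fixtures.append(
            {
                "config": cfg,
                "image": image,
                "mask": mask,
                "prediction": pred,
                "expected_counts": ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn),
            }
        )
    return fixtures
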