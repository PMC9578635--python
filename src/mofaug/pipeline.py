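"""End-to-end data path: preprocess -> augment -> class weights.

:func:`run_pipeline` reproduces the training-data preparation workflow:
every input triplet (slice, organ mask, lesion label) is windowed,
organ-cropped and resized; the training split is augmented (plain
oversampling or MOF); median-frequency class weights are computed over
the augmented training corpus; and a manifest records every parameter,
seed, accepted placement and rejection count so the whole run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as mio
from .augment import AugmentationResult, build_lesion_bank, mof_augment, oversample
from .config import RunConfig
from .metrics import SplitSpec, split_dataset
from .phantom import PhantomSpec, generate_corpus
from .preprocess import preprocess_slice
from .weighting import class_pixel_counts, weights_report

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("mofaug.pipeline")


class PipelineError(RuntimeError):
    """Raised when the run cannot produce a complete corpus."""


def _load_corpus(input_dir: Path) -> list[dict]:
    manifest_path = input_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest.json in {input_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    items = manifest.get("items")
    if not items:
        raise PipelineError("corpus manifest lists no items")
    return items


def run_pipeline(config: RunConfig) -> dict:
    """Run the full data path and return the run manifest.

    Outputs land in ``config.output_dir``: preprocessed+augmented
    image/label pairs in the configured format, ``weights.json`` with
    the median-frequency class weights over the augmented training
    split, ``histograms.csv`` with pre/post-weighting pixel masses, and
    ``manifest.json`` describing everything.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = config.format
    window = config.window.to_window()
    constraints = config.augmentation.constraints.to_constraints()
    transforms = config.augmentation.transforms.to_ranges()

    # --- input corpus -----------------------------------------------------
    if config.input_dir is None:
        phantom_dir = out_dir / "phantoms"
        spec = PhantomSpec(
            image_size=config.phantom.image_size,
            n_lesions=config.phantom.n_lesions,
            lesion_radius_range=(config.phantom.radius_min, config.phantom.radius_max),
            noise_sd=config.phantom.noise_sd,
        )
        generate_corpus(
            config.phantom.n_images, phantom_dir, spec=spec,
            seed=config.seed, fmt="png",
        )
        input_dir = phantom_dir
    else:
        input_dir = Path(config.input_dir)
    items = _load_corpus(input_dir)

    # --- split ------------------------------------------------------------
    train_idx, test_idx = split_dataset(
        len(items),
        SplitSpec(train_fraction=config.split.train_fraction, seed=config.seed),
    )
    train_set = set(int(i) for i in train_idx)

    # --- preprocess every item --------------------------------------------
    processed = []
    for item in items:
        image = mio.read_slice(input_dir / item["image"], units="HU")
        organ = mio.read_mask(input_dir / item["organ"])
        label = mio.read_mask(input_dir / item["label"])
        img, org, lab = preprocess_slice(
            image, organ, window, out_size=config.out_size, label=label
        )
        processed.append({"index": item["index"], "image": img, "organ": org,
                          "label": lab})

    # --- augment the training split ----------------------------------------
    aug = config.augmentation
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if aug.mode == "mof":
        bank = build_lesion_bank(
            [(p["image"], p["label"]) for p in processed if p["index"] in train_set]
        )
        if not bank and aug.m > 0:
            raise PipelineError("training split contains no lesions to sample")

    records = []
    for p in processed:
        is_train = p["index"] in train_set
        if is_train and aug.m > 0:
            if aug.mode == "mof":
                result = mof_augment(
                    p["image"], p["label"], p["organ"], bank, aug.m, rng,
                    constraints=constraints, transform_ranges=transforms,
                    retry_budget=aug.retry_budget,
                )
            else:
                result = oversample(
                    p["image"], p["label"], p["organ"], aug.m, rng,
                    constraints=constraints, retry_budget=aug.retry_budget,
                )
            p["image"], p["label"] = result.image, result.label
        else:
            result = AugmentationResult(image=p["image"], label=p["label"])

        stem = f"slice_{p['index']:04d}"
        image_name = f"{stem}_image.{fmt}"
        label_name = f"{stem}_label.{fmt}"
        mio.write_slice(out_dir / image_name, p["image"])
        mio.write_mask(out_dir / label_name, p["label"])
        logger.info(
            "slice %04d: split=%s accepted=%d rejected=%d",
            p["index"], "train" if is_train else "test",
            result.accepted, sum(result.rejections.values()),
        )
        records.append(
            {
                "index": p["index"],
                "split": "train" if is_train else "test",
                "image": image_name,
                "label": label_name,
                "augmentation": result.to_json(),
            }
        )

    # --- class weights over the augmented training corpus -------------------
    counts = class_pixel_counts(
        p["label"] for p in processed if p["index"] in train_set
    )
    report = weights_report(counts)
    with open(out_dir / "weights.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_histograms(out_dir / "histograms.csv", report)

    manifest = {
        "kind": "mofaug-run",
        "config": config.model_dump(),
        "train_indices": sorted(int(i) for i in train_idx),
        "test_indices": sorted(int(i) for i in test_idx),
        "items": records,
        "class_weights": report,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_histograms(path: Path, report: dict) -> None:
    """Pixel mass per class before and after weighting, as CSV."""
    lines = ["class,pixels,weighted_pixels"]
    for name, row in report.items():
        lines.append(f"{name},{row['N_c']},{row['weighted_mass']:.6f}")
    path.write_text("\n".join(lines) + "\n")
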