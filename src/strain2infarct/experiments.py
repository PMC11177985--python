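"""Experiment grid: image-size, loss-function and architecture comparisons.

Each experiment trains :class:`UNetSegmenter` models on bullseye datasets
rendered from a synthetic strain library and reports accuracy, precision,
recall, IoU and DSC on a held-out test split.  The full protocol (100
epochs, patience 5, batch size 128, image size 128) matches the library's
training defaults; the ``scaled`` flag switches to desk-scale settings
(fewer examples, reduced channel widths, fewer epochs) that preserve the
comparisons' structure at a small fraction of the cost.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import bullseye
from .estimators import UNetSegmenter
from .library import GeneratorConfig, Library, build_library
from .losses import METRIC_NAMES, metric_report
from .networks import ARCHITECTURES

logger = logging.getLogger("strain2infarct")


@dataclass
class ExperimentConfig:
    """Training protocol for one experiment."""

    name: str = "experiment"
    epochs: int = 100
    patience: int = 5
    batch_size: int = 128
    image_size: int = 128
    learning_rate: float = 1e-3
    base_channels: int = 16
    depth: int = 5
    seed: int = 0
    split_fractions: tuple = (0.7, 0.15, 0.15)
    n_examples: int | None = None   # None: use the library's size
    scaled: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def scaled_config(**overrides) -> ExperimentConfig:
    """Desk-scale defaults: a small library slice, thin networks, short
    training.  Comparisons keep their structure at a fraction of the cost."""
    base = ExperimentConfig(name="scaled", epochs=12, patience=4,
                            batch_size=16, image_size=64, learning_rate=3e-3,
                            base_channels=8, depth=4, n_examples=24,
                            scaled=True)
    return replace(base, **overrides)


def make_dataset(library: Library, config: ExperimentConfig,
                 image_size: int | None = None) -> dict:
    """Render, normalize, augment fourfold and split by source example."""
    size = image_size or config.image_size
    ranges = bullseye.default_strain_ranges(library.config)
    n = len(library.examples) if config.n_examples is None else min(
        config.n_examples, len(library.examples))
    images = [
        bullseye.example_to_image(ex, size=size, ranges=ranges, source_id=i)
        for i, ex in enumerate(library.examples[:n])
    ]
    augmented = bullseye.augment_rotations(images)
    split = bullseye.split_dataset(augmented, config.split_fractions,
                                   seed=config.seed)
    data = {}
    for name, subset in (("train", split.train), ("val", split.val),
                         ("test", split.test)):
        if subset:
            X, y = bullseye.stack_images(subset)
        else:
            X = np.zeros((0, size, size, 3), np.float32)
            y = np.zeros((0, size, size), np.uint8)
        data[f"X_{name}"], data[f"y_{name}"] = X, y
    data["manifest_hash"] = hashlib.sha256(
        library.manifest.to_csv(index=False).encode()).hexdigest()[:16]
    return data


def run_training(config: ExperimentConfig, data: dict,
                 architecture: str = "unet", loss: str = "bce"):
    """Train one model and evaluate the five metrics on the test split."""
    if data["X_train"].shape[0] == 0 or data["X_test"].shape[0] == 0:
        raise ValueError("empty train or test split")
    est = UNetSegmenter(architecture=architecture,
                        base_channels=config.base_channels,
                        depth=config.depth, loss=loss, epochs=config.epochs,
                        patience=config.patience,
                        batch_size=config.batch_size,
                        learning_rate=config.learning_rate,
                        random_state=config.seed)
    X_val = data.get("X_val")
    if X_val is not None and X_val.shape[0] == 0:
        X_val = None
    est.fit(data["X_train"], data["y_train"],
            X_val=X_val,
            y_val=data.get("y_val") if X_val is not None else None)
    pred = est.predict(data["X_test"])
    per_image = [metric_report(pred[i], data["y_test"][i])
                 for i in range(len(pred))]
    report = {m: float(np.mean([r[m] for r in per_image]))
              for m in METRIC_NAMES}
    report.update({
        "architecture": architecture,
        "loss": loss,
        "n_parameters": est.n_parameters_,
        "best_epoch": est.best_epoch_,
        "config_hash": config.config_hash(),
        "manifest_hash": data.get("manifest_hash", ""),
        "seed": config.seed,
    })
    logger.info("run_training %s", json.dumps(report, sort_keys=True))
    return est, report


def compare_image_sizes(config: ExperimentConfig, library: Library,
                        sizes=(128, 256, 512)) -> pd.DataFrame:
    """UNet with BCE loss across image sizes; one metric row per size."""
    rows = []
    for size in sizes:
        data = make_dataset(library, config, image_size=size)
        _, report = run_training(config, data, architecture="unet", loss="bce")
        rows.append({"image_size": size, **report})
    return pd.DataFrame(rows)


def compare_losses(config: ExperimentConfig, library: Library,
                   losses=("bce", "dsc", "iou")) -> pd.DataFrame:
    """UNet at fixed image size across training losses."""
    data = make_dataset(library, config)
    rows = []
    for loss in losses:
        _, report = run_training(config, data, architecture="unet", loss=loss)
        rows.append(report)
    return pd.DataFrame(rows)


def compare_architectures(config: ExperimentConfig, library: Library,
                          architectures=tuple(ARCHITECTURES)) -> pd.DataFrame:
    """All four architectures on common data and loss, with parameter counts."""
    data = make_dataset(library, config)
    rows = []
    for arch in architectures:
        _, report = run_training(config, data, architecture=arch, loss="bce")
        rows.append(report)
    return pd.DataFrame(rows)


def default_library(config: ExperimentConfig,
                    generator: GeneratorConfig | None = None,
                    domain: str = "low_fidelity") -> Library:
    gen = generator or GeneratorConfig(seed=config.seed)
    if config.n_examples is not None and config.n_examples < gen.n_examples:
        gen = replace(gen, n_examples=config.n_examples)
    return build_library(gen, domain=domain)
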