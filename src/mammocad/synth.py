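"""Synthetic fixtures: mammogram-like images and planted feature matrices.

Nothing here makes a clinical claim. The image generator renders a noisy
low-intensity background with optional bright lesion blobs — smooth
plateaus for the "benign" class, spiculated (angularly spiked) plateaus for
"malignant", none for "normal" — so the enhancement and augmentation stages
have realistic-shaped inputs. The feature generator plants a known subset
of class-informative Gaussian columns among pure-noise columns, which is
the acceptance surface for the feature selector: recovery of the planted
set is measurable because the ground truth is recorded next to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .features import FeatureMatrix
from .selection import FPcRFConfig, fitness, fpcrf_select

__all__ = [
    "ImageFixtureSpec",
    "FeatureFixtureSpec",
    "LabeledImage",
    "BenchmarkResult",
    "make_images",
    "make_features",
    "planted_recovery_benchmark",
]


@dataclass(frozen=True)
class ImageFixtureSpec:
    """Recipe for low-contrast lesion images (levels default 256)."""

    size: tuple[int, int] = (64, 64)
    n_per_class: int = 4
    background: float = 60.0
    noise_sigma: float = 5.0
    radius_range: tuple[float, float] = (6.0, 12.0)
    contrast: float = 60.0
    levels: int = 256
    classes: tuple[str, ...] = ("normal", "benign", "malignant")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("lesion contrast must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class FeatureFixtureSpec:
    """Recipe for planted-column feature matrices.

    Informative columns are Gaussian with class-dependent means separated
    by ``effect_size`` within-class standard deviations; noise columns are
    standard Gaussian independent of class.
    """

    n_per_class: int = 200
    d_informative: int = 5
    d_noise: int = 45
    effect_size: float = 2.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_informative < 1:
            raise ValueError("need at least 1 informative column")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass
class LabeledImage:
    image: np.ndarray
    label: str
    lesion_mask: np.ndarray  # boolean; all-False for lesion-free images


def _render_lesion(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    contrast: float,
    spiculated: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    edge_sigma = radius / 3.0
    blob = np.where(r <= radius, 1.0, np.exp(-((r - radius) ** 2) / (2 * edge_sigma**2)))
    if spiculated:
        theta = np.arctan2(dy, dx)
        phase = rng.uniform(0, 2 * np.pi)
        spikes = 0.5 * (1 + np.cos(8 * theta + phase))
        reach = np.exp(-((r - radius) ** 2) / (2 * (2 * edge_sigma) ** 2))
        blob = np.clip(blob + 0.6 * spikes * reach * (r > radius), 0.0, 1.2)
    return contrast * blob, r <= radius


def make_images(spec: ImageFixtureSpec) -> list[LabeledImage]:
    """Generate the labeled image set; bit-reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledImage] = []
    h, w = spec.size
    for label in spec.classes:
        for _ in range(spec.n_per_class):
            img = np.full(spec.size, spec.background, dtype=np.float64)
            mask = np.zeros(spec.size, dtype=bool)
            if label != "normal":
                radius = rng.uniform(*spec.radius_range)
                center = (
                    rng.uniform(radius + 2, h - radius - 2),
                    rng.uniform(radius + 2, w - radius - 2),
                )
                lesion, mask = _render_lesion(
                    spec.size, center, radius, spec.contrast,
                    spiculated=(label == "malignant"), rng=rng,
                )
                img += lesion
            if spec.noise_sigma > 0:
                img += rng.normal(0.0, spec.noise_sigma, size=spec.size)
            img = np.clip(img, 0.0, float(spec.levels - 1))
            out.append(LabeledImage(image=img, label=label, lesion_mask=mask))
    return out


def make_features(spec: FeatureFixtureSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Generate a planted feature matrix and its informative column indices.

    Class ``c`` has mean ``c * effect_size`` in every informative column
    (within-class sigma 1); the informative columns sit at seeded random
    positions among the noise columns. Returns ``(matrix, planted_idx)``.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.d_informative + spec.d_noise
    n = spec.n_per_class * spec.n_classes
    X = rng.standard_normal((n, d))
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    planted = np.sort(rng.choice(d, size=spec.d_informative, replace=False))
    for c in range(spec.n_classes):
        X[np.ix_(labels == c, planted)] += c * spec.effect_size
    fm = FeatureMatrix(
        values=X,
        labels=np.array([f"class{c}" for c in labels]),
        backbone_id="synthetic-planted",
        source_id=f"synth-seed{spec.seed}",
    )
    return fm, planted


@dataclass
class BenchmarkResult:
    """Planted-column recovery of the selector across seeds."""

    recall: np.ndarray  # per-seed fraction of planted columns selected
    precision: np.ndarray  # per-seed fraction of selected that are planted
    selected_sizes: np.ndarray
    error_selected: np.ndarray  # CV error of the final mask
    error_all: np.ndarray  # CV error of the all-features baseline
    seeds: np.ndarray

    @property
    def mean_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def mean_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def improvement_count(self) -> int:
        """Number of seeds where the selected subset beats all features."""
        return int(np.sum(self.error_selected < self.error_all))

    def to_dict(self) -> dict:
        return {
            "mean_recall": self.mean_recall,
            "mean_precision": self.mean_precision,
            "mean_selected_size": float(self.selected_sizes.mean()),
            "mean_error_selected": float(self.error_selected.mean()),
            "mean_error_all": float(self.error_all.mean()),
            "improvement_count": self.improvement_count,
            "n_seeds": int(self.seeds.size),
        }


def planted_recovery_benchmark(
    config: FPcRFConfig,
    spec: FeatureFixtureSpec,
    n_seeds: int = 10,
) -> BenchmarkResult:
    """Run the selector on fresh planted matrices across seeds.

    Seed ``s`` offsets both the data seed and the selector seed, so runs
    are independent but fully reproducible. The all-features baseline uses
    the same CV folds as the wrapper fitness.
    """
    recall = np.empty(n_seeds)
    precision = np.empty(n_seeds)
    sizes = np.empty(n_seeds, dtype=np.int64)
    err_sel = np.empty(n_seeds)
    err_all = np.empty(n_seeds)
    seeds = np.arange(n_seeds)
    for s in seeds:
        fspec = replace(spec, seed=spec.seed + int(s))
        cfg = replace(config, seed=config.seed + int(s))
        X, planted = make_features(fspec)
        res = fpcrf_select(X, cfg)
        sel = set(res.selected_indices.tolist())
        recall[s] = len(sel & set(planted.tolist())) / len(planted)
        precision[s] = (len(sel & set(planted.tolist())) / len(sel)) if sel else 0.0
        sizes[s] = len(sel)
        err_sel[s] = res.final_fitness
        err_all[s] = fitness(np.ones(X.n_features, dtype=bool), X, cfg)
    return BenchmarkResult(
        recall=recall,
        precision=precision,
        selected_sizes=sizes,
        error_selected=err_sel,
        error_all=err_all,
        seeds=seeds,
    )
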