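"""Per-image feature extraction behind a pluggable backbone contract.

Downstream stages (fusion, selection, evaluation) exchange a
:class:`FeatureMatrix` — an N×d real matrix with one row per image, a
per-row class label, and provenance (which backbone produced it, from
which source dataset). Any extractor producing fixed-length vectors
satisfies the contract; deep CNN features taken at a global-average-pooling
layer (d = 2048 for a ResNet50) are the intended production source, while
the deterministic *toy backbone* — a seeded random projection of the
downsampled pixels followed by tanh — makes every downstream stage
testable at desk scale without trained weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = ["FeatureMatrix", "BackboneSpec", "toy_backbone", "extract_features"]


@dataclass
class FeatureMatrix:
    """N×d feature matrix with per-row labels and provenance."""

    values: np.ndarray
    labels: np.ndarray
    backbone_id: str = "unknown"
    source_id: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.values.shape[1] < 1:
            raise ValueError("feature matrix needs at least one column")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV (feature columns + `label`), provenance as sidecar JSON."""
        path = Path(path)
        df = pd.DataFrame(
            self.values, columns=[f"f{j}" for j in range(self.n_features)]
        )
        df["label"] = self.labels
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"backbone_id": self.backbone_id, "source_id": self.source_id},
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path} has no 'label' column")
        labels = df.pop("label").to_numpy()
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            values=df.to_numpy(dtype=np.float64),
            labels=labels,
            backbone_id=meta.get("backbone_id", "unknown"),
            source_id=meta.get("source_id", "unknown"),
        )


@dataclass(frozen=True)
class BackboneSpec:
    """Description of a feature extractor producing fixed-length vectors."""

    backbone_id: str
    output_dim: int
    input_size: tuple[int, int] = (32, 32)
    deterministic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError(f"output_dim must be >= 1, got {self.output_dim}")


def toy_backbone(seed: int = 0, d: int = 64, input_size: tuple[int, int] = (32, 32)) -> BackboneSpec:
    """A deterministic stand-in extractor.

    Images are bilinearly resized to ``input_size``, flattened, passed
    through a fixed seeded Gaussian linear map to ``d`` dimensions and
    squashed with tanh. No bias term, so the zero image maps to the zero
    row; the same seed is bit-reproducible across machines.
    """
    return BackboneSpec(
        backbone_id=f"toy-seed{seed}-d{d}",
        output_dim=d,
        input_size=input_size,
        deterministic=True,
        seed=seed,
    )


def _toy_projection(spec: BackboneSpec) -> np.ndarray:
    n_in = spec.input_size[0] * spec.input_size[1]
    rng = np.random.default_rng(spec.seed)
    return rng.standard_normal((n_in, spec.output_dim)) / np.sqrt(n_in)


def extract_features(
    images: Sequence[np.ndarray],
    labels: Sequence,
    backbone: BackboneSpec,
    source_id: str = "original",
) -> FeatureMatrix:
    """Run the backbone over a batch of images, one output row per image.

    Images are resized (bilinear) to the backbone's declared input size;
    rows come out in input order. Only the toy backbone family is bundled;
    other extractors can produce a :class:`FeatureMatrix` directly.
    """
    images = list(images)
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise ValueError(f"{len(images)} images but {len(labels)} labels")
    if not backbone.backbone_id.startswith("toy"):
        raise ValueError(
            f"no bundled extractor for backbone {backbone.backbone_id!r}; "
            "construct a FeatureMatrix directly from your extractor's output"
        )
    W = _toy_projection(backbone)
    rows = np.empty((len(images), backbone.output_dim))
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError(f"image {i} is not 2-D (shape {img.shape})")
        if img.shape != backbone.input_size:
            img = resize(
                img, backbone.input_size, order=1, mode="reflect",
                anti_aliasing=False, preserve_range=True,
            )
        rows[i] = np.tanh((img.ravel() / 255.0) @ W)
    return FeatureMatrix(
        values=rows,
        labels=labels,
        backbone_id=backbone.backbone_id,
        source_id=source_id,
    )
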