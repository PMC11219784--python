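"""Training-set augmentation: rotations and contrast scaling.

The default policy expands every training image into 38 variants: 36
rotations in 10-degree steps (0-350, identity included) plus two contrast
rescalings (x0.9 and x1.1) of the unrotated image. All transforms are
deterministic; masks stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import FundusSample, ValidationError

__all__ = [
    "AugmentationPolicy",
    "TransformDescriptor",
    "enumerate_variants",
    "apply_rotation",
    "apply_contrast",
    "apply_descriptor",
    "augment_dataset",
]


@dataclass(frozen=True)
class TransformDescriptor:
    """One augmentation variant: either a rotation or a contrast change."""

    kind: str  # "rotation" | "contrast"
    angle: float = 0.0
    factor: float = 1.0

    @property
    def label(self) -> str:
        if self.kind == "rotation":
            return f"rot{int(self.angle):03d}"
        return f"con{self.factor:g}"


@dataclass
class AugmentationPolicy:
    """Rotation/contrast enumeration; defaults give 38 variants per image."""

    rotation_step: float = 10.0
    rotation_count: int = 36
    contrast_factors: list[float] = field(default_factory=lambda: [0.9, 1.1])
    seed: int = 0

    def __post_init__(self):
        if self.rotation_count < 1:
            raise ValidationError("rotation_count must be >= 1")
        if self.rotation_count * self.rotation_step > 360.0:
            raise ValidationError("rotations exceed a full turn")
        if any(f <= 0 for f in self.contrast_factors):
            raise ValidationError("contrast factors must be positive")

    @property
    def variant_count(self) -> int:
        return self.rotation_count + len(self.contrast_factors)


def enumerate_variants(policy: AugmentationPolicy) -> list[TransformDescriptor]:
    """All transform descriptors of a policy, in deterministic order:
    rotations ascending, then contrast factors as listed."""
    out = [TransformDescriptor("rotation", angle=i * policy.rotation_step)
           for i in range(policy.rotation_count)]
    out += [TransformDescriptor("contrast", factor=f) for f in policy.contrast_factors]
    return out


def _rotate_channel(arr: np.ndarray, angle: float, order: int) -> np.ndarray:
    return ndimage.rotate(arr, angle, reshape=False, order=order, mode="constant",
                          cval=0.0, prefilter=False)


def apply_rotation(sample: FundusSample, angle: float) -> FundusSample:
    """Rotate a sample about its centre (counter-clockwise, degrees).

    The image is interpolated bilinearly, masks with nearest-neighbour;
    out-of-canvas regions are filled with 0 (the black fundus border).
    Multiples of 90 degrees are exact index permutations.
    """
    if not 0.0 <= angle < 360.0:
        raise ValidationError(f"angle must lie in [0, 360), got {angle}")
    if angle == 0.0:
        return sample
    if angle % 90.0 == 0.0:
        k = int(angle // 90)
        image = np.rot90(sample.image, k, axes=(0, 1)).copy()
        mask = np.rot90(sample.vessel_mask, k).copy()
        fov = None if sample.fov_mask is None else np.rot90(sample.fov_mask, k).copy()
    else:
        image = np.clip(_rotate_channel(sample.image, angle, order=1), 0.0, 1.0)
        mask = (_rotate_channel(sample.vessel_mask.astype(np.float64), angle, order=0)
                > 0.5).astype(np.uint8)
        fov = None
        if sample.fov_mask is not None:
            fov = (_rotate_channel(sample.fov_mask.astype(np.float64), angle, order=0)
                   > 0.5).astype(np.uint8)
    return FundusSample(id=sample.id, image=image, vessel_mask=mask, fov_mask=fov,
                        source_resolution=sample.source_resolution)


def apply_contrast(sample: FundusSample, factor: float) -> FundusSample:
    """Rescale contrast linearly about the per-channel FOV mean.

    Each channel value v maps to mean + factor*(v - mean), where the mean
    is taken over field-of-view pixels (the whole frame when no FOV mask
    exists), then clips to [0, 1]. Masks are untouched.
    """
    if factor <= 0:
        raise ValidationError("contrast factor must be positive")
    sel = slice(None) if sample.fov_mask is None else sample.fov_mask.astype(bool)
    means = sample.image[sel].reshape(-1, 3).mean(axis=0)
    image = np.clip(means + factor * (sample.image - means), 0.0, 1.0)
    return FundusSample(id=sample.id, image=image, vessel_mask=sample.vessel_mask.copy(),
                        fov_mask=None if sample.fov_mask is None else sample.fov_mask.copy(),
                        source_resolution=sample.source_resolution)


def apply_descriptor(sample: FundusSample, desc: TransformDescriptor) -> FundusSample:
    out = (apply_rotation(sample, desc.angle) if desc.kind == "rotation"
           else apply_contrast(sample, desc.factor))
    return FundusSample(id=f"{sample.id}_{desc.label}", image=out.image,
                        vessel_mask=out.vessel_mask, fov_mask=out.fov_mask,
                        source_resolution=out.source_resolution)


def augment_dataset(samples: list[FundusSample],
                    policy: AugmentationPolicy) -> list[FundusSample]:
    """Expand samples by the policy; output length = len(samples) x variant_count."""
    if not samples:
        raise ValidationError("augment_dataset needs at least one sample")
    descriptors = enumerate_variants(policy)
    return [apply_descriptor(s, d) for s in samples for d in descriptors]
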