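"""Core domain containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FundusSample", "DatasetSpec", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_binary(arr: np.ndarray, name: str) -> None:
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only {{0,1}}")


@dataclass
class FundusSample:
    """One fundus photograph with its vessel annotation.

    image          HxWx3 float array in [0, 1]
    vessel_mask    HxW {0,1} array, 1 = vessel
    fov_mask       optional HxW {0,1} array marking the circular field of view
    source_resolution  (height, width) of the original file, kept so
                       predictions can be mapped back after resizing
    """

    id: str
    image: np.ndarray
    vessel_mask: np.ndarray
    fov_mask: np.ndarray | None = None
    source_resolution: tuple[int, int] | None = None

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValidationError(f"image must be HxWx3, got {self.image.shape}")
        if self.vessel_mask.shape != self.image.shape[:2]:
            raise ValidationError("vessel_mask shape differs from image")
        _check_binary(self.vessel_mask, "vessel_mask")
        if self.fov_mask is not None:
            if self.fov_mask.shape != self.image.shape[:2]:
                raise ValidationError("fov_mask shape differs from image")
            _check_binary(self.fov_mask, "fov_mask")
        if self.source_resolution is None:
            self.source_resolution = self.image.shape[:2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class DatasetSpec:
    """A named dataset plus its evaluation protocol.

    split_mode is ``fixed_train_test`` (first n_train samples train, the
    rest test — the DRIVE/HRF convention) or ``leave_one_out`` (the
    STARE/CHASE_DB1 convention).
    """

    name: str
    sample_ids: list[str] = field(default_factory=list)
    split_mode: str = "fixed_train_test"
    input_size: int = 512
    n_train: int | None = None

    def __post_init__(self):
        if self.split_mode not in ("fixed_train_test", "leave_one_out"):
            raise ValidationError(f"unknown split_mode {self.split_mode!r}")
        if self.input_size <= 0 or self.input_size % 4 != 0:
            raise ValidationError("input_size must be positive and divisible by 4 "
                                  "(two 2x poolings must invert exactly)")
        if self.split_mode == "leave_one_out" and 0 < len(self.sample_ids) < 2:
            raise ValidationError("leave_one_out needs at least 2 samples")
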