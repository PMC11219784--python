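"""Seeded synthetic fundus-like images with paired vessel and FOV masks.

The generator emulates the features the segmentation pipeline cares
about: a circular field of view on a black background, branching
curvilinear vessel trees whose width tapers from a thick trunk down to
1-pixel capillaries, vessels darker than the background by a controllable
contrast, and additive Gaussian noise. Everything is deterministic given
the seed, so full pipelines are testable without any dataset download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as _draw_disk

from .types import FundusSample, ValidationError

__all__ = ["SynthConfig", "generate_vessel_mask", "fov_disc", "render_fundus",
           "make_sample", "make_dataset"]


@dataclass
class SynthConfig:
    side: int = 256
    n_trees: int = 4
    branch_depth: int = 4
    width_range: tuple[float, float] = (1.0, 8.0)
    vessel_contrast: float = 0.35
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.side <= 0 or self.side % 4 != 0:
            raise ValidationError("side must be positive and divisible by 4")
        if self.width_range[0] <= 0 or self.width_range[1] < self.width_range[0]:
            raise ValidationError("width_range must be positive and ordered")
        if not 0.0 <= self.vessel_contrast <= 1.0:
            raise ValidationError("vessel_contrast must lie in [0,1]")
        if self.n_trees < 0 or self.branch_depth < 1:
            raise ValidationError("n_trees >= 0 and branch_depth >= 1 required")


def fov_disc(side: int, margin_frac: float = 0.04) -> np.ndarray:
    """Centred circular field-of-view mask with a small black margin."""
    r = side / 2.0 * (1.0 - margin_frac)
    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    return (((yy - c) ** 2 + (xx - c) ** 2) <= r * r).astype(np.uint8)


def _stamp(mask: np.ndarray, y: float, x: float, radius: float) -> None:
    rr, cc = _draw_disk((y, x), max(radius, 0.6), shape=mask.shape)
    mask[rr, cc] = 1


def _grow_branch(mask, rng, y, x, direction, width, depth, cfg) -> None:
    """Biased random walk drawing discs of tapering width; may bifurcate."""
    side = cfg.side
    wmin = cfg.width_range[0]
    step = max(1.0, width * 0.6)
    n_steps = int(side * (0.45 + 0.25 * rng.random()) / step)
    for _ in range(n_steps):
        _stamp(mask, y, x, width / 2.0)
        direction += rng.normal(0.0, 0.18)
        y += step * np.sin(direction)
        x += step * np.cos(direction)
        if not (0 <= y < side and 0 <= x < side):
            return
        width = max(wmin, width * 0.995)
        if depth > 1 and rng.random() < 0.035:
            split = rng.uniform(0.4, 0.9)
            _grow_branch(mask, rng, y, x, direction + rng.uniform(0.3, 0.9),
                         max(wmin, width * split), depth - 1, cfg)
            direction -= rng.uniform(0.1, 0.5)
            width = max(wmin, width * (1.1 - split))


def generate_vessel_mask(config: SynthConfig) -> np.ndarray:
    """Union of branching vessel trees, clipped to the FOV disc."""
    rng = np.random.default_rng(config.seed)
    mask = np.zeros((config.side, config.side), dtype=np.uint8)
    fov = fov_disc(config.side)
    c = (config.side - 1) / 2.0
    for _ in range(config.n_trees):
        # start near the disc centre (the optic-disc region) heading outward
        angle = rng.uniform(0, 2 * np.pi)
        r0 = config.side * rng.uniform(0.02, 0.10)
        y0 = c + r0 * np.sin(angle)
        x0 = c + r0 * np.cos(angle)
        width = rng.uniform(0.6 * config.width_range[1], config.width_range[1])
        _grow_branch(mask, rng, y0, x0, angle, width, config.branch_depth, config)
    return (mask & fov).astype(np.uint8)


def render_fundus(mask: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Render an RGB fundus-like image for a vessel mask.

    Background: smooth radial gradient inside the FOV disc (reddish, as in
    fundus photography), black outside; vessels darkened by
    ``vessel_contrast``; Gaussian noise of sd ``noise_sd`` added, clipped
    to [0,1].
    """
    if mask.shape != (config.side, config.side):
        raise ValidationError("mask shape does not match config.side")
    rng = np.random.default_rng(config.seed + 10_007)
    side = config.side
    fov = fov_disc(side).astype(np.float64)
    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) / (side / 2.0)
    base = 0.75 - 0.30 * r ** 2
    channels = [base * s for s in (1.0, 0.55, 0.30)]  # reddish cast
    img = np.stack(channels, axis=-1)
    img *= (1.0 - config.vessel_contrast * mask[:, :, None])
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img *= fov[:, :, None]
    return np.clip(img, 0.0, 1.0)


def make_sample(config: SynthConfig, sample_id: str | None = None) -> FundusSample:
    mask = generate_vessel_mask(config)
    image = render_fundus(mask, config)
    return FundusSample(id=sample_id or f"synth{config.seed:05d}",
                        image=image, vessel_mask=mask,
                        fov_mask=fov_disc(config.side),
                        source_resolution=(config.side, config.side))


def make_dataset(n: int, config: SynthConfig) -> list[FundusSample]:
    """n samples with derived seeds (config.seed + i), each a full
    image / vessel-mask / FOV triplet."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    out = []
    for i in range(n):
        cfg = SynthConfig(side=config.side, n_trees=config.n_trees,
                          branch_depth=config.branch_depth,
                          width_range=config.width_range,
                          vessel_contrast=config.vessel_contrast,
                          noise_sd=config.noise_sd, seed=config.seed + i)
        out.append(make_sample(cfg, sample_id=f"synth{cfg.seed:05d}"))
    return out
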