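"""Run configuration: one YAML file drives synth/train/predict/evaluate.

Every section is validated into its module's own type before any work
starts, and all randomness derives from the single top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import ChannelPlan
from .synth import SynthConfig
from .training import TrainingConfig
from .types import ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("runs/out")
    # dataset: either on-disk paths or synthetic parameters
    dataset: dict = field(default_factory=dict)
    model_variant: str = "full"
    channel_plan: ChannelPlan = field(default_factory=ChannelPlan)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    threshold: float = 0.5
    restrict_to_fov: bool = True

    def synth_config(self) -> SynthConfig:
        d = self.dataset
        return SynthConfig(
            side=int(d.get("side", 256)),
            n_trees=int(d.get("n_trees", 4)),
            branch_depth=int(d.get("branch_depth", 4)),
            width_range=tuple(d.get("width_range", (1.0, 8.0))),
            vessel_contrast=float(d.get("vessel_contrast", 0.35)),
            noise_sd=float(d.get("noise_sd", 0.02)),
            seed=self.seed,
        )

    @property
    def n_samples(self) -> int:
        return int(self.dataset.get("n", 4))

    @property
    def input_size(self) -> int:
        return int(self.dataset.get("input_size", self.dataset.get("side", 256)))


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a mapping")
    seed = int(raw.get("seed", 0))
    model = raw.get("model", {}) or {}
    plan_kwargs = {k: v for k, v in model.items() if k != "variant"}
    if "encoder_channels" in plan_kwargs:
        plan_kwargs["encoder_channels"] = tuple(plan_kwargs["encoder_channels"])
    if "decoder_channels" in plan_kwargs:
        plan_kwargs["decoder_channels"] = tuple(plan_kwargs["decoder_channels"])
    training_raw = dict(raw.get("training", {}) or {})
    training_raw.setdefault("seed", seed)
    evaluation = raw.get("evaluation", {}) or {}
    return RunConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "runs/out")),
        dataset=dict(raw.get("dataset", {}) or {}),
        model_variant=model.get("variant", "full"),
        channel_plan=ChannelPlan(**plan_kwargs),
        training=TrainingConfig(**training_raw),
        threshold=float(evaluation.get("threshold", 0.5)),
        restrict_to_fov=bool(evaluation.get("restrict_to_fov", True)),
    )
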