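"""End-to-end runs: synthesise data, train, predict, evaluate.

These functions are the programmatic face of the command-line tool; each
writes its artefacts (PNG triplets, history CSV, checkpoints, metric
tables, overlays) under the config's output directory and returns the
in-memory results as well.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import io as fio
from .config import RunConfig
from .network import build_ablation_variant, build_network, count_parameters
from .synth import make_dataset
from .training import samples_to_arrays, train
from .types import FundusSample, ValidationError

__all__ = ["run_synth", "run_train", "run_predict", "run_evaluate"]

log = logging.getLogger("lmbisnet")


def _ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def _echo_config(config: RunConfig, out: Path) -> None:
    payload = {"seed": config.seed, "dataset": config.dataset,
               "model_variant": config.model_variant,
               "threshold": config.threshold,
               "restrict_to_fov": config.restrict_to_fov}
    (out / "effective_config.json").write_text(json.dumps(payload, indent=2))


def run_synth(config: RunConfig) -> list[FundusSample]:
    """Write n synthetic image/mask/FOV PNG triplets plus a manifest."""
    out = _ensure_dir(config.output_dir / "synth")
    _echo_config(config, _ensure_dir(config.output_dir))
    samples = make_dataset(config.n_samples, config.synth_config())
    manifest = []
    for s in samples:
        import imageio.v3 as iio

        iio.imwrite(out / f"{s.id}_image.png",
                    (s.image * 255).round().astype(np.uint8), extension=".png")
        fio.write_mask(s.vessel_mask, out / f"{s.id}_mask.png")
        fio.write_mask(s.fov_mask, out / f"{s.id}_fov.png")
        manifest.append(s.id)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("synth: wrote %d triplets to %s", len(samples), out)
    return samples


def _build(config: RunConfig):
    if config.model_variant == "full":
        return build_network(config.channel_plan, seed=config.seed)
    return build_ablation_variant(config.model_variant, seed=config.seed)


def _load_synth_samples(config: RunConfig) -> list[FundusSample]:
    synth_dir = config.output_dir / "synth"
    manifest_path = synth_dir / "manifest.json"
    if manifest_path.exists():
        ids = json.loads(manifest_path.read_text())
        return [fio.load_sample(i, synth_dir / f"{i}_image.png",
                                synth_dir / f"{i}_mask.png",
                                synth_dir / f"{i}_fov.png") for i in ids]
    return make_dataset(config.n_samples, config.synth_config())


def run_train(config: RunConfig, max_steps: int | None = None):
    """Train on the configured dataset; writes checkpoint, history CSV and
    the per-layer parameter table. Aborts before training on a parameter
    budget violation."""
    out = _ensure_dir(config.output_dir)
    graph = _build(config)
    (out / "parameter_table.csv").write_text(graph.parameter_table_csv())
    samples = _load_synth_samples(config)
    samples = [fio.resize_to_input(s, config.input_size) for s in samples]
    n_val = max(1, len(samples) // 10)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(samples))
    val = [samples[i] for i in order[:n_val]]
    trn = [samples[i] for i in order[n_val:]] or val
    state, history = train(graph, trn, val, config.training, max_steps=max_steps)
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    np.savez(out / "checkpoint.npz", **state)
    log.info("train: %d epochs, params=%d", len(history), count_parameters(graph))
    return graph, history


def run_predict(config: RunConfig, checkpoint: str | Path | None = None):
    """Predict masks (and probability maps) for the dataset at source
    resolution, using a trained checkpoint."""
    out = _ensure_dir(config.output_dir / "predictions")
    graph = _build(config)
    ckpt = Path(checkpoint) if checkpoint else config.output_dir / "checkpoint.npz"
    if not ckpt.exists():
        raise ValidationError(f"checkpoint not found: {ckpt}")
    with np.load(ckpt) as data:
        state = {k: data[k] for k in data.files}
    try:
        graph.model.set_state(state)
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"checkpoint {ckpt} incompatible with model plan: {exc}") from exc
    samples = _load_synth_samples(config)
    results = []
    for s in samples:
        rs = fio.resize_to_input(s, config.input_size)
        x, _ = samples_to_arrays([rs])
        probs = graph.model.forward(x, training=False)[0, 1]
        probs_src = fio.restore_resolution(probs, s.source_resolution, binary=False)
        mask = ev.binarize_prediction(probs_src, config.threshold)
        fio.write_mask(mask, out / f"{s.id}_pred.png")
        np.savetxt(out / f"{s.id}_prob.csv", probs_src, delimiter=",", fmt="%.5f")
        results.append((s.id, mask, probs_src))
    log.info("predict: wrote %d masks to %s", len(results), out)
    return results


def run_evaluate(config: RunConfig, predictions_dir: str | Path | None = None):
    """Evaluate predicted masks against ground truth; writes the per-image
    CSV, a summary JSON (fractions and percents) and error overlays."""
    pred_dir = Path(predictions_dir) if predictions_dir else config.output_dir / "predictions"
    out = _ensure_dir(config.output_dir / "metrics")
    samples = _load_synth_samples(config)
    preds, gts, fovs, ids = [], [], [], []
    missing = []
    for s in samples:
        p = pred_dir / f"{s.id}_pred.png"
        if not p.exists():
            missing.append(s.id)
            continue
        preds.append(fio.read_mask(p))
        gts.append(s.vessel_mask)
        fovs.append(s.fov_mask if config.restrict_to_fov else None)
        ids.append(s.id)
    if missing:
        raise ValidationError(f"missing predictions for ids: {missing}")
    summary, table = ev.evaluate_dataset(preds, gts, fovs, ids)
    table.to_csv(out / "per_image_metrics.csv", index=False)
    (out / "summary.json").write_text(json.dumps(
        {"fraction": summary.as_fraction(), "percent": summary.as_percent()}, indent=2))
    import imageio.v3 as iio

    for sid, p, g in zip(ids, preds, gts):
        iio.imwrite(out / f"{sid}_overlay.png", ev.render_error_overlay(p, g),
                    extension=".png")
    log.info("evaluate: mean Acc=%.4f over %d images", summary.acc, len(ids))
    return summary, table
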