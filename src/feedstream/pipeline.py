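"""End-to-end pipeline: scenes → stream features → training → fusion → report.

One call runs the whole method on synthetic feeding scenes: generate a
balanced labeled clip set, split it at clip level (70/20/10 by default),
extract the three stream representations per consecutive-frame pair —
rendered optical-flow image, binary splash image, GLCM descriptor — train
the three classifiers independently, and evaluate single streams, all
stream pairs and the fused three-stream decision on the held-out test
clips, at frame and at clip level.

Streams are aligned per item: the sample for frame t (t >= 1) of a clip is
the flow image of the pair (t−1, t), the binary image of frame t, and the
GLCM vector of frame t, so fusion operates on one score triple per item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage.transform import resize

from .binarize import binarize
from .config import RunConfig, config_to_dict, dump_config
from .dataio import LABELS, SplitSpec, split_manifest, stratified_split
from .flow import estimate_flow, flow_to_image, to_grayscale
from .fusion import STREAM_NAMES, aggregate_clip, fuse_scores, run_ablation
from .glcm import feature_vector
from .metrics import MetricsReport, compute_metrics, confusion_matrix
from .nn.conv1d import build_conv1d_net
from .nn.resnet import ResidualBackboneConfig, build_residual_backbone
from .nn.train import TrainConfig, predict_proba, save_model, train_stream
from .synth import LabeledSequence, generate_dataset

__all__ = ["StreamArrays", "PipelineResult", "extract_stream_samples", "end_to_end"]

LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class StreamArrays:
    """Aligned per-item sample arrays of one partition."""

    temporal: np.ndarray  # (N, 3, H, W) flow images in [0, 1]
    spatial: np.ndarray  # (N, 3, H, W) binary images in {0, 1}
    glcm: np.ndarray  # (N, 1, L) descriptors (unstandardized)
    y: np.ndarray  # (N,) integer labels
    clip_ids: list  # (N,) source_id per item

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class PipelineResult:
    """Everything an end-to-end run produced."""

    report: dict
    models: dict
    histories: dict
    test_arrays: StreamArrays
    stream_scores: dict
    glcm_stats: tuple[np.ndarray, np.ndarray]
    run_dir: Optional[Path]


def _resize_to(img: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == hw:
        return img
    return resize(img, hw, order=1, preserve_range=True, anti_aliasing=True)


def extract_stream_samples(
    clips: list,
    config: RunConfig,
    image_hw: Optional[tuple[int, int]] = None,
) -> StreamArrays:
    """Extract the three aligned stream representations for a clip list.

    ``clips`` may hold :class:`~feedstream.synth.LabeledSequence` objects or
    labeled :class:`~feedstream.dataio.FrameSequence` objects.
    """
    temporal, spatial, glcm_rows, ys, ids = [], [], [], [], []
    for clip in clips:
        fs = clip.frames if hasattr(clip.frames, "frames") else clip
        frames = fs.frames
        gray = [to_grayscale(f) for f in frames]
        for t in range(1, len(frames)):
            flow = estimate_flow(
                gray[t - 1],
                gray[t],
                smoothness_weight=config.flow.smoothness_weight,
                n_iterations=config.flow.n_iterations,
            )
            flow_img = flow_to_image(flow, max_magnitude=config.flow.max_magnitude)
            binary = binarize(frames[t], config.binarization)
            if image_hw is not None:
                flow_img = _resize_to(flow_img.astype(np.float64), image_hw)
                binary = _resize_to(binary.astype(np.float64), image_hw)
            temporal.append(np.asarray(flow_img, dtype=np.float64).transpose(2, 0, 1) / 255.0)
            bin_plane = np.asarray(binary, dtype=np.float64) / 255.0
            spatial.append(np.repeat(bin_plane[None], 3, axis=0))
            glcm_rows.append(feature_vector(frames[t], config.glcm).values)
            ys.append(LABEL_INDEX[clip.label])
            ids.append(fs.source_id)
    return StreamArrays(
        temporal=np.stack(temporal),
        spatial=np.stack(spatial),
        glcm=np.stack(glcm_rows)[:, None, :],
        y=np.array(ys),
        clip_ids=ids,
    )


def _backbone_config(config: RunConfig, hw: tuple[int, int]) -> ResidualBackboneConfig:
    if config.backbone.profile == "reduced":
        return ResidualBackboneConfig(
            stage_block_counts=(1, 1, 1, 1),
            input_size=(hw[0], hw[1], 3),
            base_width=8,
        )
    return ResidualBackboneConfig(input_size=(hw[0], hw[1], 3))


def _standardize(glcm: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (glcm - mean) / std


def _clip_level(
    clip_ids: list, true_idx: np.ndarray, predicted: list[str]
) -> tuple[list[str], list[str]]:
    order: list = []
    frames_of: dict = {}
    truth: dict = {}
    for cid, t, p in zip(clip_ids, true_idx, predicted):
        if cid not in frames_of:
            frames_of[cid] = []
            order.append(cid)
            truth[cid] = LABELS[int(t)]
        frames_of[cid].append(p)
    return [truth[c] for c in order], [aggregate_clip(frames_of[c]) for c in order]


def end_to_end(config: RunConfig, out_dir: Optional[Path] = None) -> PipelineResult:
    """Run the full method at the scale set by ``config``.

    Writes (when ``out_dir`` is given) the frozen effective config, split
    manifest, per-stream training histories and checkpoints, and the final
    JSON report under one run directory. A fixed ``config.seed`` makes the
    whole run — data, splits, initialization, training — reproducible.
    """
    hw = (config.data.frame_height, config.data.frame_width)
    clips = generate_dataset(
        config.data.n_per_class,
        seed=config.seed,
        frame_size=hw,
        n_frames=config.data.n_frames,
        fps=config.data.fps,
    )

    split_spec = SplitSpec(
        train_frac=config.split.train_frac,
        test_frac=config.split.test_frac,
        val_frac=config.split.val_frac,
        seed=config.seed,
        unit=config.split.unit,
    )
    train_clips, test_clips, val_clips = stratified_split(clips, split_spec)

    backbone_cfg = _backbone_config(config, hw)
    image_hw = None
    if backbone_cfg.input_size[:2] != hw:
        image_hw = backbone_cfg.input_size[:2]

    parts = {
        name: extract_stream_samples(part, config, image_hw=image_hw)
        for name, part in (("train", train_clips), ("test", test_clips), ("val", val_clips))
    }
    tr, te, va = parts["train"], parts["test"], parts["val"]

    # GLCM descriptors are standardized with train-partition moments.
    g_mean = tr.glcm.mean(axis=0)
    g_std = tr.glcm.std(axis=0)
    g_std[g_std == 0] = 1.0

    stream_inputs = {
        "temporal": (tr.temporal, te.temporal, va.temporal),
        "spatial": (tr.spatial, te.spatial, va.spatial),
        "glcm": (
            _standardize(tr.glcm, g_mean, g_std),
            _standardize(te.glcm, g_mean, g_std),
            _standardize(va.glcm, g_mean, g_std),
        ),
    }

    models, histories, summaries = {}, {}, {}
    for k, name in enumerate(STREAM_NAMES):
        stream_seed = (config.seed * 1000003 + k) % (2**31)
        if name == "glcm":
            model = build_conv1d_net(config.conv1d, seed=stream_seed)
            summaries[name] = {"type": "conv1d", "input_length": config.conv1d.input_length}
        else:
            model, summaries[name] = build_residual_backbone(backbone_cfg, seed=stream_seed)
        tcfg = TrainConfig(
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            learning_rate=config.train.learning_rate,
            seed=stream_seed,
        )
        X_tr, _, X_va = stream_inputs[name]
        histories[name] = train_stream(model, X_tr, tr.y, tcfg, X_val=X_va, y_val=va.y)
        models[name] = model

    stream_scores = {
        name: predict_proba(models[name], stream_inputs[name][1]) for name in STREAM_NAMES
    }

    true_labels = [LABELS[i] for i in te.y]
    ablation = run_ablation(stream_scores, true_labels, method=config.fusion.method)

    fused_labels = [
        fuse_scores([stream_scores[n][i] for n in STREAM_NAMES], method=config.fusion.method).label
        for i in range(len(te))
    ]
    clip_true, clip_pred = _clip_level(te.clip_ids, te.y, fused_labels)
    clip_report = compute_metrics(
        confusion_matrix(clip_true, clip_pred), averaging=config.fusion.averaging
    )

    def _key(combo: tuple[str, ...]) -> str:
        return "+".join(combo)

    report = {
        "n_clips": len(clips),
        "n_train_items": len(tr),
        "n_test_items": len(te),
        "n_val_items": len(va),
        "streams": {
            name: ablation[(name,)].to_dict() for name in STREAM_NAMES
        },
        "ablation": {_key(c): r.to_dict() for c, r in ablation.items()},
        "fused_frame_level": ablation[STREAM_NAMES].to_dict(),
        "fused_clip_level": clip_report.to_dict(),
        "final_history": {
            name: histories[name].iloc[-1].to_dict() for name in STREAM_NAMES
        },
    }

    run_dir = None
    if out_dir is not None:
        run_dir = Path(out_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        dump_config(config, run_dir / "config.yaml")
        split_manifest(
            (train_clips, test_clips, val_clips),
            label_of=lambda c: c.label,
            id_of=lambda c: c.frames.source_id,
        ).to_csv(run_dir / "split_manifest.csv", index=False)
        for name in STREAM_NAMES:
            histories[name].to_csv(run_dir / f"history_{name}.csv", index=False)
            save_model(models[name], run_dir / f"model_{name}.npz", summary=summaries[name])
        (run_dir / "report.json").write_text(json.dumps(report, indent=2))

    return PipelineResult(
        report=report,
        models=models,
        histories=histories,
        test_arrays=te,
        stream_scores=stream_scores,
        glcm_stats=(g_mean, g_std),
        run_dir=run_dir,
    )
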