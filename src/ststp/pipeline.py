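"""Run configuration and the end-to-end pipeline:
keyframes -> modality features -> fusion -> selection -> model -> evaluation.

Every stochastic stage receives a seed derived from the master seed, so a
re-run with identical config and inputs reproduces identical feature CSVs
and metrics byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, synthgen
from .eyes import EAR_FEATURE_NAMES, ear_feature_block
from .hands import pose_matrix
from .io_formats import (FeatureTable, LandmarkStream, VideoClip,
                         read_landmarks, read_video, write_feature_table,
                         write_report)
from .keyframes import select_keyframes
from .model import Encoder, EncoderConfig, Hyperparams, resize_frames
from .motion import MOTION_FEATURE_NAMES, motion_features

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


def _from_mapping(cls, mapping, where):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class KeyframeParams:
    P: float = 1.0


@dataclass
class MotionParams:
    max_corners: int = 100
    quality: float = 0.3
    min_distance: int = 7
    block_size: int = 7
    window: int = 15
    max_level: int = 4


@dataclass
class HandsParams:
    n_components: int = 10


@dataclass
class EyesParams:
    blink_threshold: float = 0.2
    blink_min_frames: int = 2
    clahe: bool = False
    iris_radius_min: int = 2
    iris_radius_max: int = 10


@dataclass
class SelectionParams:
    enabled: bool = False
    tol: float = 0.01
    gate_factor: float = 0.0


@dataclass
class ModelParams:
    encoder_input: int = 32
    embedding_dim: int = 8
    hidden: int = 100
    batch_size: int = 32
    dropout: float = 0.2
    max_epochs: int = 64
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 5e-4

    def hyperparams(self) -> Hyperparams:
        return Hyperparams(hidden=self.hidden, batch_size=self.batch_size,
                           dropout=self.dropout, max_epochs=self.max_epochs,
                           lr=self.lr, momentum=self.momentum,
                           weight_decay=self.weight_decay)


@dataclass
class EvalParams:
    k: int = 10


@dataclass
class SimulateParams:
    n_per_class: int = 10
    effect: float = 1.0
    n_frames: int = 200
    fps: float = 25.0
    frame_size: int = 64


@dataclass
class RunConfig:
    """Per-module parameter blocks plus the master seed."""

    keyframe: KeyframeParams = field(default_factory=KeyframeParams)
    motion: MotionParams = field(default_factory=MotionParams)
    hands: HandsParams = field(default_factory=HandsParams)
    eyes: EyesParams = field(default_factory=EyesParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    model: ModelParams = field(default_factory=ModelParams)
    eval: EvalParams = field(default_factory=EvalParams)
    simulate: SimulateParams = field(default_factory=SimulateParams)
    seed: int = 0
    output_dir: str = "ststp_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        blocks = {}
        known = {f.name: f for f in fields(cls)}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for name, f in known.items():
            if name in ("seed", "output_dir"):
                continue
            sub = mapping.get(name, {})
            blocks[name] = _from_mapping(f.default_factory, sub, name)
        return cls(seed=int(mapping.get("seed", 0)),
                   output_dir=str(mapping.get("output_dir", "ststp_out")),
                   **blocks)


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------

def extract_blocks(clip: VideoClip, stream: LandmarkStream,
                   config: RunConfig | None = None,
                   encoder: Encoder | None = None) -> dict:
    """Extract all modality blocks for one clip, aligned on its keyframes.

    Returns a dict with keys KEYFRAMES, CNN, OF, HAND_RAW, EAR; every block
    has one row per kept keyframe.  The raw hand-pose block (HAND_RAW) is
    reduced to its PCA projection later, inside training folds, to avoid
    leakage.
    """
    config = config or RunConfig()
    if len(stream) != len(clip):
        raise DataError(
            f"clip {clip.clip_id}: landmark stream length {len(stream)} "
            f"!= frame count {len(clip)}")
    kf = select_keyframes(clip, config.keyframe.P)
    if kf.n_kept < 2:
        raise DataError(f"clip {clip.clip_id}: fewer than 2 keyframes kept")
    if encoder is None:
        encoder = default_encoder(config)
    m = config.motion
    of_vec = motion_features(clip, kf, m.max_corners, m.quality,
                             m.min_distance, m.block_size, m.window,
                             m.max_level)
    size = encoder.config.input_size[:2]
    frames = resize_frames(clip.frames[kf.kept], size)
    cnn = encoder.forward(frames)
    hand_raw = pose_matrix(stream, kf.kept)
    ear = ear_feature_block(stream, kf.kept)
    return {"KEYFRAMES": kf, "CNN": cnn, "OF": of_vec,
            "HAND_RAW": hand_raw, "EAR": ear}


def default_encoder(config: RunConfig) -> Encoder:
    s = config.model.encoder_input
    enc_cfg = EncoderConfig(
        input_size=(s, s, 3),
        layers=[("conv", 6, 3, 2, "same"), ("pool", 2, 2),
                ("conv", 12, 3, 2, "same"),
                ("fc", config.model.embedding_dim), ("fc", 2)])
    return Encoder(enc_cfg, seed=config.seed)


def blocks_to_table(blocks: dict, label: str, clip_id: str,
                    n_components: int | None = None,
                    pca_model=None) -> FeatureTable:
    """Per-keyframe feature rows (raw hand block included) as a table."""
    kf = blocks["KEYFRAMES"]
    cols = {}
    cols["keyframe"] = kf.kept
    for i in range(blocks["CNN"].shape[1]):
        cols[f"cnn_{i}"] = blocks["CNN"][:, i]
    for i, name in enumerate(MOTION_FEATURE_NAMES):
        cols[name] = blocks["OF"][:, i]
    for i in range(blocks["HAND_RAW"].shape[1]):
        cols[f"hand_{i}"] = blocks["HAND_RAW"][:, i]
    for i, name in enumerate(EAR_FEATURE_NAMES):
        cols[name] = blocks["EAR"][:, i]
    return FeatureTable(data=pd.DataFrame(cols), label=label, clip_id=clip_id)


def table_to_blocks(table: FeatureTable) -> dict:
    df = table.data
    cnn_cols = sorted([c for c in df.columns if c.startswith("cnn_")],
                      key=lambda c: int(c.split("_")[1]))
    hand_cols = sorted([c for c in df.columns if c.startswith("hand_")],
                       key=lambda c: int(c.split("_")[1]))
    return {
        "CNN": df[cnn_cols].to_numpy(float),
        "OF": df[list(MOTION_FEATURE_NAMES)].to_numpy(float),
        "HAND_RAW": df[hand_cols].to_numpy(float),
        "EAR": df[list(EAR_FEATURE_NAMES)].to_numpy(float),
    }


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def simulate_cohort(config: RunConfig):
    sim = config.simulate
    base = synthgen.ScenarioConfig(
        n_frames=sim.n_frames, fps=sim.fps,
        frame_size=(sim.frame_size, sim.frame_size))
    return synthgen.generate_cohort(sim.n_per_class, sim.effect,
                                    seed=config.seed, base=base)


def run_pipeline(config: RunConfig, manifest: list[dict] | None = None,
                 output_dir: str | None = None) -> dict:
    """Execute every stage in order and write the artifacts.

    ``manifest`` lists {"clip": path, "landmarks": path, "label": LIE|TRUTH}
    entries; when None, a synthetic cohort is simulated from the config's
    ``simulate`` block.  Returns a summary dict (also written as JSON).
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate" if manifest is None else "load"
    current = None
    try:
        if manifest is None:
            subjects = simulate_cohort(config)
            clips = [s.clip for s in subjects]
            streams = [s.landmarks for s in subjects]
            labels = [s.label for s in subjects]
            log.info("simulate: %d subjects", len(subjects))
        else:
            clips, streams, labels = [], [], []
            for entry in manifest:
                for key in ("clip", "landmarks", "label"):
                    if key not in entry:
                        raise DataError(f"manifest entry missing '{key}': {entry}")
                clip_path = Path(entry["clip"])
                lm_path = Path(entry["landmarks"])
                if not clip_path.exists():
                    raise DataError(f"missing clip file: {clip_path}")
                if not lm_path.exists():
                    raise DataError(f"missing landmark file: {lm_path}")
                clips.append(read_video(clip_path))
                streams.append(read_landmarks(lm_path))
                labels.append(str(entry["label"]))
            log.info("load: %d clips", len(clips))

        stage = "extract"
        encoder = default_encoder(config)
        raw_blocks = []
        feature_dir = out / "features"
        current = None
        for clip, stream, label in zip(clips, streams, labels):
            current = clip.clip_id
            blocks = extract_blocks(clip, stream, config, encoder)
            raw_blocks.append(blocks)
            table = blocks_to_table(blocks, label, clip.clip_id)
            write_feature_table(table, feature_dir / f"{clip.clip_id}.csv")
            log.info("extract %s: %d/%d keyframes", clip.clip_id,
                     blocks["KEYFRAMES"].n_kept, len(clip))
        current = None

        stage = "evaluate"
        blocks_only = [{k: b[k] for k in ("CNN", "OF", "HAND_RAW", "EAR")}
                       for b in raw_blocks]
        outcomes, pooled = evaluate.kfold_evaluate(
            blocks_only, labels, k=config.eval.k,
            n_components=config.hands.n_components,
            use_selection=config.selection.enabled,
            selection_tol=config.selection.tol,
            hyper=config.model.hyperparams(), seed=config.seed)
        report = {"config_seed": config.seed, "n_subjects": len(labels),
                  "pooled": pooled.as_dict(), "folds": pooled.folds}
        write_report(report, out / "eval_report.json")
        return report
    except Exception as exc:
        where = f" (clip {current})" if current else ""
        raise type(exc)(f"stage '{stage}'{where}: {exc}") from exc
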