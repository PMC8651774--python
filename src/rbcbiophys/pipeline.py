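"""End-to-end orchestration: simulate → segment → measure → deform → classify.

``run_pipeline`` executes the whole chain on synthetic classes and writes a
versioned result bundle (images, masks, CSVs, JSON summaries, optional model
archive) plus a manifest with the config hash, so a rerun with the same
config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as _io
from .classifier import ClassifierConfig, FeatureMode, SampleDataset, preprocess, train
from .deformability import deformability_summary, match_cells, pairs_to_frame
from .morphometry import chamber_volume_ml, measure_regions, morphometry_to_frame, summarize
from .segmentation import segment_frame
from .synthgen import DEFAULT_PROFILES, ClassProfile, SceneConfig, save_scene, simulate_scene

logger = logging.getLogger("rbcbiophys")

__all__ = ["RunConfig", "run_pipeline", "analyze_scene"]


@dataclass
class RunConfig:
    """Parameters of one full synthetic run.

    Every stochastic stage receives a seed derived deterministically from
    ``master_seed``.
    """

    output_dir: str = "rbc_run"
    classes: tuple[str, ...] = ("healthy", "IDA")
    samples_per_class: int = 12
    scene: SceneConfig = field(default_factory=SceneConfig)
    master_seed: int = 0
    max_disp_um: float = 3.0
    train_classifier: bool = True
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    chamber_depth_um: float = 20.0
    dilution: float = 1.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        c = dict(self.classifier.__dict__)
        c["feature_mode"] = self.classifier.feature_mode.value
        c["fc_sizes"] = list(self.classifier.fc_sizes)
        d["classifier"] = c
        d["classes"] = list(self.classes)
        return d


def analyze_scene(
    pre,
    post,
    max_disp_um: float = 3.0,
    chamber_depth_um: float = 20.0,
    dilution: float = 1.0,
):
    """Segment a pre/post pair, measure morphometry, match cells, compute Dr.

    Returns (summary: PopulationSummary, detail dict of tables/objects).
    """
    kept_pre, _ = segment_frame(pre)
    kept_post, _ = segment_frame(post)
    cells = measure_regions(kept_pre, pre.pixel_scale)
    pairs, un_pre, un_post = match_cells(kept_pre, kept_post, pre.pixel_scale, max_disp_um)
    drs = [p.dr for p in pairs]
    h_um, w_um = pre.physical_extent()
    volume = chamber_volume_ml(w_um, h_um, chamber_depth_um, dilution)
    summary = summarize(cells, drs=drs or None, volume_ml=volume)
    if pairs:
        dr_summary, dr_table = deformability_summary(pairs)
    else:
        dr_summary, dr_table = None, pairs_to_frame([])
    return summary, {
        "regions_pre": kept_pre,
        "regions_post": kept_post,
        "cells": cells,
        "pairs": pairs,
        "n_unmatched_pre": len(un_pre),
        "n_unmatched_post": len(un_post),
        "dr_summary": dr_summary,
        "dr_table": dr_table,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic pipeline and write the result bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    master = np.random.SeedSequence(entropy=(int(config.master_seed), 0x9B0D1))
    class_seeds = master.spawn(len(config.classes))

    all_params: list[np.ndarray] = []
    all_images: list[np.ndarray] = []
    all_labels: list[int] = []
    summaries: list[dict] = []
    for ci, cls in enumerate(config.classes):
        stage_t = time.time()
        try:
            profile = DEFAULT_PROFILES[cls] if cls in DEFAULT_PROFILES else ClassProfile(cls)
            sample_seeds = class_seeds[ci].generate_state(config.samples_per_class)
            for si in range(config.samples_per_class):
                scene = dataclasses.replace(
                    config.scene, seed=int(sample_seeds[si] % (2**31 - 1))
                )
                pre, post, truth = simulate_scene(profile, scene)
                sample_dir = out / "scenes" / f"{cls}_{si:03d}"
                if si == 0:  # keep one full scene per class on disk
                    save_scene(sample_dir, pre, post, truth, scene, profile)
                summary, detail = analyze_scene(
                    pre, post, config.max_disp_um, config.chamber_depth_um, config.dilution
                )
                if si == 0:
                    _io.save_regions_csv(sample_dir / "regions_pre.csv", detail["regions_pre"])
                    morphometry_to_frame(detail["cells"]).to_csv(
                        sample_dir / "morphometry.csv", index=False
                    )
                    detail["dr_table"].to_csv(sample_dir / "pairs.csv", index=False)
                vec = summary.vector()
                all_params.append(vec)
                all_images.append(preprocess(pre, crop_mm=config.classifier.crop_mm))
                all_labels.append(ci)
                summaries.append(
                    {"class": cls, "sample": si, **summary.to_dict()}
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'simulate/analyze' failed for class {cls!r}") from exc
        logger.info("class %s: %d samples in %.1fs", cls, config.samples_per_class, time.time() - stage_t)

    pd.DataFrame(summaries).to_csv(out / "population_summaries.csv", index=False)

    metrics: dict = {}
    if config.train_classifier and len(config.classes) >= 2:
        stage_t = time.time()
        try:
            cfg = dataclasses.replace(
                config.classifier,
                n_classes=len(config.classes),
                seed=int(config.master_seed),
            )
            dataset = SampleDataset(
                params=np.vstack(all_params),
                labels=np.asarray(all_labels),
                images=np.stack(all_images) if cfg.feature_mode.uses_image else None,
                class_names=list(config.classes),
            )
            result = train(dataset, cfg)
            result.model.save(out / "model.npz")
            metrics = {
                "cycle_accuracies": result.cycle_accuracies,
                "mean_accuracy": float(np.mean(result.cycle_accuracies)),
                "confusion": result.final_confusion.tolist(),
            }
        except Exception as exc:
            raise RuntimeError("pipeline stage 'train' failed") from exc
        logger.info("training done in %.1fs", time.time() - stage_t)

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "classifier_metrics": metrics,
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
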