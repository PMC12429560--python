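"""End-to-end orchestration: synth -> train -> predict -> measure -> analyze.

Each stage reads only the previous stage's serialized outputs, so a run can
be resumed after deleting any suffix of the stage outputs. One global seed
fans out to per-stage and per-section seeds through a fixed
``SeedSequence(entropy=seed, spawn_key=(counter,))`` scheme, so extending a
cohort never reshuffles existing sections. Re-running with an identical
config reproduces all CSV outputs bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scio
from .densito import (
    partition_segments, measure, records_to_frame, compute_RI, compute_ISMP,
    ismp_group_summary,
)
from .segment import TrainConfig, TrainedModel, train, predict, tile_image
from .stats import analyze_cohort, analyze_ismp, heatmap_tables, render_heatmaps
from .synth import SynthesisConfig, EffectTable, iter_cohort
from .types import (
    LabelMap, SectionImage, MATRIX, STRIOSOME, REFERENCE_MOLECULE,
)
from .unet import UNetSpec


@dataclass
class PipelineConfig:
    out_dir: str = "striocompart_run"
    seed: int = 0
    n_mice_per_group: int = 4
    molecules: list[str] | None = None
    synthesis: dict = field(default_factory=dict)   # SynthesisConfig overrides
    unet: dict = field(default_factory=dict)        # UNetSpec overrides
    train: dict = field(default_factory=dict)       # TrainConfig overrides
    family_size: int = 10
    skip_train: bool = False   # use ground-truth striosome masks downstream
    figures: bool = True
    stages: list[str] = field(default_factory=lambda: [
        "synth", "train", "predict", "measure", "analyze"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**scio.load_yaml(path))

    def synthesis_config(self) -> SynthesisConfig:
        base = dict(image_height_px=256, image_width_px=256, seed=self.seed)
        base.update(self.synthesis)
        return SynthesisConfig(**base)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _train_config(cfg: PipelineConfig) -> TrainConfig:
    base = dict(batch_size=16, total_epochs=8, tile_size=64,
                steps_per_epoch=4, learning_rate=2e-3, seed=cfg.seed)
    base.update(cfg.train)
    return TrainConfig(**base)


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Execute the enabled stages in order; returns the report directory.

    Existing stage outputs are reused unless ``force`` — deleting only the
    report directory and rerunning reproduces it exactly from cached stage
    outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    runners = {
        "synth": _stage_synth, "train": _stage_train,
        "predict": _stage_predict, "measure": _stage_measure,
        "analyze": _stage_analyze,
    }
    for stage in cfg.stages:
        if stage not in runners:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            runners[stage](cfg, out, force)
        except Exception as exc:
            _write_manifest(cfg, out, timings, failed=stage)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
    _write_manifest(cfg, out, timings)
    return out / "report"


def _write_manifest(cfg, out: Path, timings: dict, failed: str | None = None):
    from . import __version__

    manifest = {
        "config": asdict(cfg), "config_hash": cfg.config_hash(),
        "version": __version__, "stage_seconds": timings,
    }
    if failed:
        manifest["failed_stage"] = failed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def measure_cohort(effects: EffectTable, n_mice_per_group: int,
                   scfg: SynthesisConfig, molecules=None) -> pd.DataFrame:
    """Generate a cohort in memory and run ground-truth densitometry on it;
    returns the tidy per-sample records table (streaming, images are not
    retained)."""
    records = []
    for img, lab, meta in iter_cohort(effects, n_mice_per_group, scfg,
                                      molecules=molecules):
        parts = partition_segments(lab.striatal,
                                   medial_side=meta["medial_side"])
        records.extend(measure(
            img, lab, parts,
            animal=meta["animal"], hemisphere=meta["hemisphere"],
            molecule=meta["molecule"], genotype=meta["genotype"],
            age=meta["age"]))
    return records_to_frame(records)


# -- stages ------------------------------------------------------------------

def _stage_synth(cfg: PipelineConfig, out: Path, force: bool) -> None:
    meta_csv = out / "sections" / "metadata.csv"
    if meta_csv.exists() and not force:
        return
    (out / "sections").mkdir(exist_ok=True)
    scfg = cfg.synthesis_config()
    effects = EffectTable.default(scfg.background_level)
    rows = []
    for i, (img, lab, meta) in enumerate(iter_cohort(
            effects, cfg.n_mice_per_group, scfg, molecules=cfg.molecules)):
        sid = f"sec{i:04d}"
        ref, tgt = scio.save_section(out / "sections" / sid, img)
        scio.save_labelmap(out / "sections" / f"{sid}_labels.png", lab)
        rows.append({"section": sid, **meta,
                     "ref_path": ref.name, "target_path": tgt.name,
                     "labels_path": f"{sid}_labels.png"})
    pd.DataFrame(rows).to_csv(meta_csv, index=False)
    scio.save_config(out / "sections" / "synthesis.yaml", scfg)
    effects.to_frame().to_csv(out / "sections" / "effects.csv", index=False)


def _stage_train(cfg: PipelineConfig, out: Path, force: bool) -> None:
    if cfg.skip_train:
        return
    ckpt = out / "model.npz"
    if ckpt.exists() and not force:
        return
    meta = pd.read_csv(out / "sections" / "metadata.csv")
    ref_rows = meta[meta["molecule"] == REFERENCE_MOLECULE]
    if ref_rows.empty:  # cohort without the reference molecule: train on all
        ref_rows = meta
    tcfg = _train_config(cfg)
    tiles = []
    for _, row in ref_rows.iterrows():
        img = scio.load_channel(out / "sections" / row["ref_path"])
        lab = scio.load_labelmap(out / "sections" / row["labels_path"])
        for t, tl, _ in tile_image(img, lab, tcfg.tile_size, drop_empty=True):
            tiles.append((t, tl))
    spec = UNetSpec(**cfg.unet)
    model, curve = train(tiles, spec, tcfg)
    model.save(ckpt)
    curve.to_frame().to_csv(out / "training_curve.csv", index=False)


def _stage_predict(cfg: PipelineConfig, out: Path, force: bool) -> None:
    pred_dir = out / "pred_masks"
    if cfg.skip_train:
        return
    meta = pd.read_csv(out / "sections" / "metadata.csv")
    if pred_dir.exists() and not force and \
            len(list(pred_dir.glob("*.png"))) == len(meta):
        return
    pred_dir.mkdir(exist_ok=True)
    model = TrainedModel.load(out / "model.npz")
    for _, row in meta.iterrows():
        img = scio.load_channel(out / "sections" / row["ref_path"])
        truth = scio.load_labelmap(out / "sections" / row["labels_path"])
        _, pred = predict(model, img, striatal_mask=truth.striatal)
        scio.save_labelmap(pred_dir / f"{row['section']}_pred.png", pred)


def _stage_measure(cfg: PipelineConfig, out: Path, force: bool) -> None:
    rec_csv = out / "records.csv"
    if rec_csv.exists() and not force:
        return
    meta = pd.read_csv(out / "sections" / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        ref = scio.load_channel(out / "sections" / row["ref_path"])
        tgt = scio.load_channel(out / "sections" / row["target_path"])
        truth = scio.load_labelmap(out / "sections" / row["labels_path"])
        compartments = truth
        if not cfg.skip_train:
            pred = scio.load_labelmap(
                out / "pred_masks" / f"{row['section']}_pred.png")
            # predicted striosomes within the striatal territory; the
            # remaining striatal pixels are matrix, exclusions from truth
            lab = truth.labels.copy()
            lab[truth.striatal] = MATRIX
            lab[truth.striatal & pred.striosome] = STRIOSOME
            compartments = LabelMap(lab)
        section = SectionImage(ref, tgt,
                               channel_names=(REFERENCE_MOLECULE, row["molecule"]))
        parts = partition_segments(truth.striatal,
                                   medial_side=row["medial_side"])
        records.extend(measure(
            section, compartments, parts,
            exclusions=truth.excluded_structures,
            background_region=truth.background,
            animal=row["animal"], hemisphere=row["hemisphere"],
            molecule=row["molecule"], genotype=row["genotype"],
            age=int(row["age"]),
        ))
    records_to_frame(records).to_csv(rec_csv, index=False)


def _stage_analyze(cfg: PipelineConfig, out: Path, force: bool) -> None:
    report = out / "report"
    if (report / "heatmap_RI.csv").exists() and not force:
        return
    report.mkdir(exist_ok=True)
    rec = pd.read_csv(out / "records.csv")
    ri = compute_RI(rec[rec["genotype"] == "Q175KI"],
                    rec[rec["genotype"] == "WT"])
    ismp = compute_ISMP(rec)
    stat = analyze_cohort(rec, family_size=cfg.family_size)
    ismp_stat = analyze_ismp(ismp, family_size=cfg.family_size)
    tables = heatmap_tables(ri, stat, compartment="striosome")
    tables["RI"].to_csv(report / "heatmap_RI.csv")
    tables["effect"].to_csv(report / "heatmap_effect.csv")
    tables["significant"].to_csv(report / "heatmap_significant.csv")
    ri.to_csv(report / "ri.csv", index=False)
    stat.to_csv(report / "stats.csv", index=False)
    ismp.to_csv(report / "ismp.csv", index=False)
    ismp_group_summary(ismp).merge(
        ismp_stat, on=["molecule", "age", "segment"], how="left"
    ).to_csv(report / "ismp_summary.csv", index=False)
    if cfg.figures:
        render_heatmaps(tables, str(report / "heatmap"))
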