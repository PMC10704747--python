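"""End-to-end pipeline: geometry → leadfield → datasets → sweep → stats."""

from __future__ import annotations

import logging
import pathlib

import numpy as np
import pandas as pd

from cuffsim import experiments as ex
from cuffsim import io as io_mod
from cuffsim import models as models_mod
from cuffsim import simulate as sim_mod
from cuffsim.config import PipelineConfig, config_hash
from cuffsim.forward import Leadfield, VoxelForwardProblem, build_leadfield
from cuffsim.geometry import (
    CrossSectionModel,
    build_fine_electrode,
    extrude_volume,
    synthesize_cross_section,
)

log = logging.getLogger("cuffsim")


def build_geometry(config: PipelineConfig) -> CrossSectionModel:
    g = config.geometry
    return synthesize_cross_section(
        seed=g.seed,
        n_fascicles=g.n_fascicles,
        epineurium_semi_axes=g.epineurium_semi_axes,
        fascicle_radius_range=g.fascicle_radius_range,
        min_centroid_separation=g.min_centroid_separation,
        pixel_pitch=g.pixel_pitch,
        perineurium_fraction=g.perineurium_fraction,
    )


def compute_leadfield(
    config: PipelineConfig,
    cross_section: CrossSectionModel | None = None,
    cache_dir: str | pathlib.Path | None = None,
    progress: bool = False,
) -> Leadfield:
    """Build (or load from cache) the tripolar-referenced leadfield.

    The cache key hashes the geometry and forward config sections, so a
    change to either invalidates the cached matrix.
    """
    key = config_hash(config, "geometry", "forward")
    if cache_dir is not None:
        cache_path = pathlib.Path(cache_dir) / f"leadfield_{key}.h5"
        if cache_path.exists():
            log.info("leadfield cache hit: %s", cache_path)
            return io_mod.read_leadfield(cache_path, expected_hash=key)
    cross_section = cross_section or build_geometry(config)
    layout = build_fine_electrode()
    volume = extrude_volume(
        cross_section,
        layout,
        axial_length=config.geometry.axial_length,
        axial_pitch=config.geometry.axial_pitch,
        saline_diameter=config.geometry.saline_diameter,
    )
    problem = VoxelForwardProblem(
        volume,
        insulator_cutoff=config.forward.insulator_cutoff,
        tolerance=config.forward.tolerance,
    )
    log.info("solving leadfield: %d unknowns", problem.n_unknowns)
    leadfield = build_leadfield(
        problem,
        layout,
        reference_contact=config.forward.reference_contact,
        progress=progress,
    )
    if cache_dir is not None:
        pathlib.Path(cache_dir).mkdir(parents=True, exist_ok=True)
        io_mod.write_leadfield(leadfield, cache_path, config_hash=key)
        log.info("leadfield cached: %s", cache_path)
    return leadfield


def waveform_bank(config: PipelineConfig) -> sim_mod.WaveformBank:
    s = config.simulate
    return sim_mod.generate_waveform_bank(
        seed=s.waveform_seed,
        n_templates=s.n_templates,
        n_samples=s.n_samples,
        sampling_rate=s.sampling_rate,
        amplitude_jitter=s.amplitude_jitter,
        offset_jitter=s.offset_jitter,
    )


def model_spec(config: PipelineConfig, n_classes: int) -> models_mod.ModelSpec:
    m = config.model
    return models_mod.ModelSpec(
        backbone=m.backbone,
        n_classes=n_classes,
        width_mult=m.width_mult,
        dropout=m.dropout,
    )


def train_config(config: PipelineConfig) -> models_mod.TrainConfig:
    m = config.model
    patience = m.patience
    if patience is None:
        patience = 15 if m.backbone == "escape" else 40
    return models_mod.TrainConfig(
        learning_rate=m.learning_rate,
        lr_decay=m.lr_decay,
        momentum=m.momentum,
        patience=patience,
        max_epochs=m.max_epochs,
        batch_size=m.batch_size,
        val_fraction=m.val_fraction,
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | pathlib.Path,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run the configured sweep; write tidy CSVs and a JSON summary.

    Returns the tidy accuracy table (condition, repetition, fold,
    accuracy).  The leadfield is computed once and reused across all
    conditions; the ANOVA table is written whenever both factors have at
    least two levels and at least two repetitions.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cross_section = build_geometry(config)
    leadfield = compute_leadfield(
        config, cross_section, cache_dir=out_dir / "cache", progress=verbose
    )
    bank = waveform_bank(config)
    sw = config.sweep
    results = []
    for c in sw.class_counts:
        for n in sw.noise_ratios:
            log.info("condition: %d classes, %.0f%% noise", c, 100 * n)
            res = ex.run_condition(
                leadfield,
                bank,
                cross_section,
                class_count=c,
                noise_ratio=n,
                repetitions=sw.repetitions,
                dataset_size=sw.dataset_size,
                model_spec=model_spec(config, c),
                train_config=train_config(config),
                folds=sw.folds,
                master_seed=config.master_seed,
                verbose=verbose,
            )
            results.append(res)
    table = pd.concat([r.rows for r in results], ignore_index=True)
    table.to_csv(out_dir / "accuracies.csv", index=False)
    summary = (
        table.groupby(["class_count", "noise", "repetition"])["accuracy"]
        .mean()
        .groupby(["class_count", "noise"])
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.to_csv(out_dir / "summary.csv", index=False)
    if (
        len(sw.class_counts) > 1
        and len(sw.noise_ratios) > 1
        and sw.repetitions > 1
    ):
        rep_means = (
            table.groupby(["class_count", "noise", "repetition"])["accuracy"]
            .mean()
            .reset_index()
            .rename(columns={"accuracy": "value"})
        )
        anova = ex.two_way_anova(rep_means)
        anova.to_csv(out_dir / "anova.csv")
    return table


def run_desk_benchmark(
    seed: int = 1,
    class_count: int = 3,
    noise_ratio: float = 0.05,
    dataset_size: int = 6000,
    repetitions: int = 3,
    folds: int = 3,
    cache_dir: str | pathlib.Path | None = None,
    verbose: bool = False,
) -> ex.ConditionResult:
    """The desk-scale reference condition: 3 classes at 5% noise.

    Synthesizes the 17-fascicle geometry (>= 1 mm centroid separation),
    computes the leadfield, generates balanced 6,000-sample signature
    datasets and trains the desk-width two-stream CNN with the standard
    hyperparameters, reporting accuracy over repetitions x folds.
    """
    config = PipelineConfig(master_seed=seed)
    config = config.model_copy(
        update={"geometry": config.geometry.model_copy(update={"seed": seed})}
    )
    cross_section = build_geometry(config)
    leadfield = compute_leadfield(
        config, cross_section, cache_dir=cache_dir, progress=verbose
    )
    bank = waveform_bank(config)
    return ex.run_condition(
        leadfield,
        bank,
        cross_section,
        class_count=class_count,
        noise_ratio=noise_ratio,
        repetitions=repetitions,
        dataset_size=dataset_size,
        model_spec=model_spec(config, class_count),
        train_config=train_config(config),
        folds=folds,
        master_seed=seed,
        verbose=verbose,
    )
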