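"""End-to-end analysis pipeline and the canonical study configurations.

Stages: synthetic campaign (or ingested data) -> background segmentation ->
feature embedding -> species-level elevation regression -> representative
images -> 100-m assemblages -> diversity trend with pairwise and family
bootstraps -> 1-D trait axis and T-statistics -> melanism indices ->
path model -> JSON-serialisable report.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import assemblage as asmb
from . import colour, features, pathmodel, segmentation, tstats
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "standard_config",
    "null_config",
    "colour_only_config",
    "structural_config",
]

logger = logging.getLogger("elevcolour")

# per-100-m species counts emulating the reported collecting regime:
# 19 populated intervals, smallest assemblage 11 species
STRUCTURAL_BIN_COUNTS = (
    11, 12, 14, 17, 21, 25, 28, 30, 28, 25, 22, 20, 18, 16, 15, 14, 13, 12, 11,
)
STRUCTURAL_GAPS = (
    (500.0, 600.0),
    (1300.0, 1400.0),
    (1800.0, 1900.0),
    (2000.0, 2100.0),
    (2200.0, 2300.0),
    (2400.0, 2500.0),
)


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig
    variant: str = "colour"
    dim: int = features.DEFAULT_DIM
    bin_width: float = 100.0
    pairwise_reps: int = 5000
    pairwise_m: int | None = None
    family_reps: int = 1000
    family_draw: int = 4
    run_family_bootstrap: bool = True
    use_segmentation: bool = True
    ridge_alpha: float = 1.0
    validation_fraction: float = 0.2
    seed: int = 0


def standard_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Planted-effect study conditions: thermal melanism plus external
    filtering, balanced 10-species bins over 0-2500 m."""
    gen = GeneratorConfig(
        n_species=250,
        images_per_species=(2, 4),
        species_per_bin=(10,) * 25,
        melanism_slope_b=-0.2,
        melanism_slope_s=0.12,
        forewing_melanism_bias=-0.05,
        external_filter_strength=0.5,
        filter_includes_brightness=True,
        elevation_sd=150.0,
        seed=seed,
    )
    return PipelineConfig(generator=replace(gen, **overrides), seed=seed)


def null_config(seed: int = 0, **overrides) -> PipelineConfig:
    """No planted effects: flat colour structure, balanced 11-species bins,
    single-locality species (the coverage-calibration condition)."""
    gen = GeneratorConfig(
        n_species=275,
        images_per_species=(2, 3),
        species_per_bin=(11,) * 25,
        melanism_slope_b=0.0,
        melanism_slope_s=0.0,
        forewing_melanism_bias=0.0,
        external_filter_strength=0.0,
        elevation_sd=0.0,
        seed=seed,
    )
    return PipelineConfig(generator=replace(gen, **overrides), seed=seed)


def colour_only_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Chromatic-only planted signal: saturation trend and chromatic scatter
    shrinkage, no brightness trend - the greyscale-control condition."""
    gen = GeneratorConfig(
        n_species=250,
        images_per_species=(2, 4),
        species_per_bin=(10,) * 25,
        melanism_slope_b=0.0,
        melanism_slope_s=0.12,
        forewing_melanism_bias=0.0,
        external_filter_strength=0.5,
        filter_includes_brightness=False,
        elevation_sd=150.0,
        seed=seed,
    )
    return PipelineConfig(generator=replace(gen, **overrides), seed=seed)


def structural_config(seed: int = 0, **overrides) -> PipelineConfig:
    """The reported collecting regime, scaled to desk size: 0-2500 m with six
    unsampled 100-m intervals (19 assemblages), smallest assemblage 11
    species (55 pairwise distances), single-locality species."""
    gen = GeneratorConfig(
        n_species=sum(STRUCTURAL_BIN_COUNTS),
        images_per_species=(1, 3),
        elevation_gaps=STRUCTURAL_GAPS,
        species_per_bin=STRUCTURAL_BIN_COUNTS,
        melanism_slope_b=-0.2,
        melanism_slope_s=0.12,
        forewing_melanism_bias=-0.05,
        external_filter_strength=0.5,
        elevation_sd=0.0,
        seed=seed,
    )
    return PipelineConfig(generator=replace(gen, **overrides), seed=seed)


def _foreground_masks(
    dataset: SyntheticDataset, config: PipelineConfig
) -> tuple[dict[str, np.ndarray], list[segmentation.SegmentationReport]]:
    masks, reports = {}, []
    for image_id, img in dataset.images.items():
        truth = dataset.masks[image_id]
        if config.use_segmentation:
            mask, rep = segmentation.segment_image(img, image_id, truth=truth)
            reports.append(rep)
        else:
            mask = truth > 0
        masks[image_id] = mask
    return masks, reports


def _elevation_model_stats(
    vectors: dict[str, np.ndarray],
    meta: pd.DataFrame,
    species_mean: pd.Series,
    config: PipelineConfig,
) -> dict:
    """Image-level 80/20 split, per-species averaged validation predictions,
    species-level R^2 (the protocol of the elevation-prediction task)."""
    rng = np.random.default_rng(config.seed + 1)
    ids = meta["image_id"].to_numpy()
    n_val = max(1, int(round(config.validation_fraction * len(ids))))
    val_ids = set(rng.choice(ids, size=n_val, replace=False))
    train = meta[~meta["image_id"].isin(val_ids)]
    val = meta[meta["image_id"].isin(val_ids)]
    if train["species_id"].nunique() < 2:
        raise ValueError("too few species to fit the elevation model")
    x_train = np.stack([vectors[i] for i in train["image_id"]])
    y_train = species_mean.loc[train["species_id"]].to_numpy()
    model = features.fit_elevation_model(x_train, y_train, alpha=config.ridge_alpha)
    preds, actual = [], []
    for sp, grp in val.groupby("species_id"):
        x = np.stack([vectors[i] for i in grp["image_id"]])
        preds.append(features.predict_species_elevation(model, x))
        actual.append(float(species_mean.loc[sp]))
    preds_a, actual_a = np.array(preds), np.array(actual)
    ss_res = float(((actual_a - preds_a) ** 2).sum())
    ss_tot = float(((actual_a - actual_a.mean()) ** 2).sum())
    return {
        "training_mse": model.training_mse,
        "validation_species": int(len(preds)),
        "validation_r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on one synthetic campaign; returns the report dict."""
    t0 = time.time()
    dataset = generate_dataset(config.generator)
    meta = dataset.metadata
    logger.info("simulate: %d species, %d images", len(dataset.species), len(meta))

    fg_masks, seg_reports = _foreground_masks(dataset, config)
    seg_summary = None
    if seg_reports:
        mious = [r.miou for r in seg_reports if r.miou is not None]
        seg_summary = {
            "n_images": len(seg_reports),
            "mean_miou": float(np.mean(mious)) if mious else None,
            "min_miou": float(np.min(mious)) if mious else None,
        }
    logger.info("segment: done (%s)", seg_summary)

    vectors = {
        image_id: features.embed(
            dataset.images[image_id],
            fg_masks[image_id],
            variant=config.variant,
            dim=config.dim,
            part_mask=dataset.masks[image_id],
        )
        for image_id in meta["image_id"]
    }
    species_mean = dataset.species_mean_elevations()

    elev_stats = _elevation_model_stats(vectors, meta, species_mean, config)
    logger.info("elevation model: %s", elev_stats)

    # representative image and vector per species
    rep_ids = {
        sp: features.representative_image(grp, float(species_mean.loc[sp]))
        for sp, grp in meta.groupby("species_id")
    }
    rep_vectors = {sp: vectors[i] for sp, i in rep_ids.items()}

    assemblages = asmb.bin_species(species_mean, width=config.bin_width)
    usable = [a for a in assemblages if a.n_species >= 2]
    records = [asmb.within_diversity(a, rep_vectors) for a in usable]
    x_mid = [r.midpoint for r in records]
    div_trend = asmb.fit_trend(x_mid, [r.diversity for r in records])
    boot_pair = asmb.bootstrap_pairwise(
        usable, rep_vectors, m=config.pairwise_m,
        reps=config.pairwise_reps, seed=config.seed + 2,
    )
    boot_family = None
    if config.run_family_bootstrap:
        fam_of = meta.drop_duplicates("species_id").set_index("species_id")["family_id"]
        boot_family = asmb.bootstrap_family(
            usable, rep_vectors, fam_of.to_dict(),
            n_families=config.family_draw, reps=config.family_reps,
            seed=config.seed + 3,
        )
    logger.info("diversity: %d assemblages, slope %.3g", len(records), div_trend.slope)

    # assemblage-level climate covariates
    sp_climate = meta.groupby("species_id")[["temperature_c", "precip_mm"]].mean()
    bin_of = {s: a.label for a in usable for s in a.species}
    label_mid = {a.label: a.midpoint for a in usable}
    clim = (
        sp_climate.assign(assemblage=[bin_of.get(s) for s in sp_climate.index])
        .dropna(subset=["assemblage"])
        .groupby("assemblage")
        .mean()
    )

    # one common 1-D trait axis over the regional pool of individuals
    img_ids = list(meta["image_id"])
    all_vec = np.stack([vectors[i] for i in img_ids])
    elev_of_img = species_mean.loc[meta.set_index("image_id").loc[img_ids, "species_id"]].to_numpy()
    axis = features.mds_project(
        features.pairwise_cosine(all_vec), dims=1, orient_by=elev_of_img
    )[:, 0]
    obs = pd.DataFrame(
        {
            "image_id": img_ids,
            "species_id": meta.set_index("image_id").loc[img_ids, "species_id"].to_numpy(),
            "trait": axis,
        }
    )
    obs["assemblage"] = obs["species_id"].map(bin_of)
    obs = obs.dropna(subset=["assemblage"])
    obs["midpoint"] = obs["assemblage"].map(label_mid)
    trecords = tstats.compute_tstats(obs)
    t_mid = [r.midpoint for r in trecords]
    t_temp = clim.loc[[r.label for r in trecords], "temperature_c"].to_numpy()
    t_prec = clim.loc[[r.label for r in trecords], "precip_mm"].to_numpy()
    tstat_trends = {
        "t_ic_ir_elevation": tstats.tstat_trend(trecords, t_mid, "t_ic_ir"),
        "t_ic_ir_temperature": tstats.tstat_trend(trecords, t_temp, "t_ic_ir"),
        "t_ic_ir_precipitation": tstats.tstat_trend(trecords, t_prec, "t_ic_ir"),
        "t_ip_ic_elevation": tstats.tstat_trend(trecords, t_mid, "t_ip_ic"),
        "t_ip_ic_temperature": tstats.tstat_trend(trecords, t_temp, "t_ip_ic"),
        "t_ip_ic_precipitation": tstats.tstat_trend(trecords, t_prec, "t_ip_ic"),
    }
    logger.info("tstats: %d assemblages", len(trecords))

    # melanism indices on representative images (ground-truth part masks)
    idx_of_sp = {
        sp: colour.specimen_indices(dataset.images[i], dataset.masks[i])
        for sp, i in rep_ids.items()
    }
    asm_rows = []
    for a in usable:
        b_mean, s_mean = colour.assemblage_indices(idx_of_sp[s] for s in a.species)
        asm_rows.append(
            {"assemblage": a.label, "midpoint": a.midpoint,
             "b_index": b_mean, "s_index": s_mean}
        )
    asm_table = pd.DataFrame(asm_rows).set_index("assemblage")
    asm_table["temperature"] = clim["temperature_c"]
    asm_table["t_ic_ir"] = {r.label: r.t_ic_ir for r in trecords}
    melanism_trends = {
        "b_elevation": asmb.fit_trend(asm_table["midpoint"], asm_table["b_index"]),
        "b_temperature": asmb.fit_trend(asm_table["temperature"], asm_table["b_index"]),
        "s_elevation": asmb.fit_trend(asm_table["midpoint"], asm_table["s_index"]),
        "s_temperature": asmb.fit_trend(asm_table["temperature"], asm_table["s_index"]),
    }
    path_fit = pathmodel.fit_path(asm_table)
    sat_check = pathmodel.fit_saturation_check(asm_table)
    logger.info("path model: indirect effect %.3f", path_fit.indirect_effect)

    return {
        "config": dataclasses.asdict(config),
        "n_species": len(dataset.species),
        "n_images": int(len(meta)),
        "segmentation": seg_summary,
        "elevation_model": elev_stats,
        "structure": {
            "n_assemblages": len(records),
            "min_assemblage_species": int(min(r.n_species for r in records)),
            "max_assemblage_species": int(max(r.n_species for r in records)),
            "trend_df": div_trend.df,
            "pairwise_draw_size": _pairwise_draw_size(usable, config.pairwise_m),
        },
        "diversity": {
            "records": records,
            "trend": div_trend,
            "bootstrap_pairwise": boot_pair,
            "bootstrap_family": boot_family,
        },
        "tstats": {"records": trecords, "trends": tstat_trends},
        "melanism": {"assemblage_table": asm_table.reset_index(),
                     "trends": melanism_trends},
        "path": {"fit": path_fit, "saturation_check": sat_check},
        "runtime_s": time.time() - t0,
    }


def _pairwise_draw_size(usable, m: int | None) -> int:
    if m is not None:
        return m
    nmin = min(a.n_species for a in usable)
    return nmin * (nmin - 1) // 2
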