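"""End-to-end orchestration: simulate -> unmix -> segment -> identify ->
quantify -> spatial correlation, with reproducible run reports."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from . import io as cio
from .dipole import DipoleSettings, dipole_correlation, peak_stats
from .identify import (
    build_cell_table,
    classify_all,
    default_crossreaction_rules,
    exclude_crossreactive,
    measure_rois,
)
from .panel import ProbePanel, default_panel, load_panel
from .quantify import FOVGeometry, group_summary
from .segment import SegmentationParams, robust_noise_sd, segment_channel
from .synth import (
    SceneConfig,
    ground_truth_table,
    preset_config,
    render_spectral,
    sample_scene,
    synthetic_reference_spectra,
)
from .unmix import ReferenceSpectra, unmix

logger = logging.getLogger("clasifish")

__all__ = ["RunConfig", "analyze_image", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    """Everything needed to reproduce an end-to-end run."""

    images: list[dict]  # each: {path, sample_id, fov_id, site, tissue}
    out_dir: str
    panel_path: str | None = None
    spectra_path: str | None = None
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    identify_factor: float = 2.0
    dipole_settings: DipoleSettings = field(default_factory=DipoleSettings)
    run_dipole: bool = False
    seed: int = 0


def analyze_image(
    image,
    panel: ProbePanel,
    spectra: ReferenceSpectra,
    seg_params: SegmentationParams | None = None,
    identify_factor: float = 2.0,
    fov_meta: dict | None = None,
    keep_ambiguous: bool = False,
):
    """Quantify one spectral image: unmix, segment each quantified taxon's
    channel, exclude cross-reactions, classify, and build the cell table.

    Returns ``(cell_table, taxon_masks, report)`` where ``taxon_masks`` maps
    each leaf taxon to the binary mask of its conclusively identified cells
    (the input to spatial-arrangement analysis).
    """
    seg_params = seg_params or SegmentationParams()
    t0 = time.time()
    stack = unmix(image.data, spectra, nonneg=True, pixel_size_um=image.pixel_size_um)
    # remove the unmixed share of the flat autofluorescent background so the
    # intensity-ratio rule compares probe signals, not offsets
    bg = np.median(stack.abundances, axis=(0, 1))
    noise_sd = {
        dye: robust_noise_sd(stack.channel(dye)) for dye in stack.dyes
    }
    stack.abundances = np.clip(stack.abundances - bg, 0.0, None)
    report: dict = {"unmix_seconds": round(time.time() - t0, 2), "channels": {}}
    rules = default_crossreaction_rules(panel)
    all_rois = []
    masks = {}
    px = image.pixel_size_um
    for taxon in panel.leaf_taxa():
        dye = panel.taxon_channel(taxon)
        channel = stack.channel(dye)
        method = seg_params.method_for(taxon)
        # maxima tolerance per channel, from the pre-subtraction noise scale:
        # dense coccoid channels use a tighter tolerance to split clusters
        chan_params = replace(
            seg_params,
            maxima_prominence=seg_params.maxima_prominence
            or seg_params.prominence_multiplier_for(taxon) * noise_sd[dye],
        )
        labels, seg_report = segment_channel(channel, method, chan_params, px)
        rois = measure_rois(labels, stack, source_channel=dye)
        # positivity floor: a cell must actually carry signal in the channel
        # it was segmented from, not just win the ratio against zeros
        floor = 3.0 * noise_sd[dye]
        rois = [r for r in rois if r.mean_intensity[dye] >= floor]
        rois = exclude_crossreactive(rois, rules)
        rois = classify_all(rois, panel, identify_factor)
        kept_ids = {r.roi_id for r in rois if r.conclusive}
        masks[taxon] = np.isin(labels.labels, list(kept_ids)) if kept_ids else (
            np.zeros_like(labels.labels, dtype=bool)
        )
        report["channels"][taxon] = {
            **seg_report,
            "n_conclusive": len(kept_ids),
            "n_rois": len(rois),
        }
        all_rois.extend(rois)
        logger.info(
            "%s: %d ROIs, %d conclusive", taxon, len(rois), len(kept_ids)
        )
    table = build_cell_table(all_rois, fov_meta, keep_ambiguous=keep_ambiguous)
    return table, masks, report


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline over the configured images and write outputs.

    Writes the combined cell table CSV, a density report CSV, optional
    dipole curve CSVs, and a JSON run report with every effective parameter;
    identical config + seed give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    if config.spectra_path:
        spectra = ReferenceSpectra.from_csv(config.spectra_path)
    else:
        spectra = synthetic_reference_spectra(panel.dye_list)
    tables = []
    report = {
        "seed": config.seed,
        "identify_factor": config.identify_factor,
        "segmentation": {
            "bernsen_radius_px": config.seg_params.bernsen_radius_px,
            "bernsen_contrast": config.seg_params.bernsen_contrast,
            "maxima_prominence": config.seg_params.maxima_prominence,
            "min_object_area_um2": config.seg_params.min_object_area_um2,
        },
        "images": [],
    }
    masks_by_image = {}
    for entry in config.images:
        path = Path(entry["path"])
        if not path.exists():
            raise FileNotFoundError(f"stage unmix: spectral image not found: {path}")
        image = cio.read_spectral_tiff(path)
        meta = {k: v for k, v in entry.items() if k != "path"}
        table, masks, img_report = analyze_image(
            image,
            panel,
            spectra,
            config.seg_params,
            config.identify_factor,
            fov_meta=meta,
        )
        for col in ("site", "tissue"):
            if col not in table.columns:
                table[col] = meta.get(col, "")
        tables.append(table)
        masks_by_image[entry.get("fov_id", path.stem)] = masks
        report["images"].append({"path": str(path), **img_report})
    cells = (
        pd.concat(tables, ignore_index=True)
        if tables
        else build_cell_table([], None)
    )
    cells.to_csv(out / "cell_table.csv", index=False)
    geom = FOVGeometry(
        side_um=image.pixel_size_um * image.data.shape[0], px=image.data.shape[0]
    )
    if not cells.empty and "site" in cells.columns:
        summary = group_summary(cells, geom, group_col="site")
        summary.to_csv(out / "density_report.csv", index=False)
        report["density_report"] = "density_report.csv"
    if config.run_dipole:
        curves = {}
        # filament-dominated taxa are excluded from arrangement analysis
        for fov_id, masks in masks_by_image.items():
            for taxon, mask in masks.items():
                if taxon == C.BACTEROIDETES or not mask.any():
                    continue
                settings = config.dipole_settings
                curve = dipole_correlation(
                    mask, mask, settings, image.pixel_size_um,
                    apply_noise_exclusion=True,
                )
                name = f"dipole_{fov_id}_{taxon.replace('/', '-')}.csv"
                curve.to_frame().to_csv(out / name, index=False)
                stats = peak_stats(curve)
                curves[name] = {
                    "peak_um": stats.peak_distance_um,
                    "fwhm_um": stats.fwhm_um,
                }
        report["dipole"] = curves
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def make_fixtures(
    preset: str,
    seed: int = 0,
    px: int = 512,
    out_dir: str | None = None,
    snr: float = 10.0,
):
    """Generate a ground-truthed synthetic image bundle for a survey preset.

    The scene is parameterized to the preset's published per-taxon mean
    counts, scaled to the requested image size at constant pixel size.
    Returns (image, scene, panel, spectra); with ``out_dir`` also writes the
    spectral TIFF, ground-truth CSV, and per-taxon mask TIFFs.
    """
    panel = default_panel()
    config = preset_config(preset, px=px, seed=seed, snr=snr, panel=panel)
    scene = sample_scene(config)
    spectra = synthetic_reference_spectra(panel.dye_list)
    image = render_spectral(scene, panel, spectra, config)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_spectral_tiff(image, out / f"{preset}_{seed}.tiff")
        ground_truth_table(scene).to_csv(
            out / f"{preset}_{seed}_truth.csv", index=False
        )
        for taxon, mask in scene.masks.items():
            cio.write_mask_tiff(
                mask > 0, out / f"{preset}_{seed}_{taxon.replace('/', '-')}.tiff"
            )
    return image, scene, panel, spectra
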