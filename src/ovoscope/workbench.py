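"""Orchestration and I/O glue: simulate -> measure -> analyze.

A YAML config (with a mandatory ``seed``) drives three commands:

* ``simulate`` writes a fixture directory of synthetic egg image pairs
  (16-bit TIFF), JSON truth sidecars, a truth trait CSV, and a manifest
  with SHA-256 checksums of every artifact;
* ``measure`` runs radiometry -> spot segmentation -> UV alignment ->
  morphometry on each egg of such a directory and writes one flat per-egg
  CSV report (partial failures are row-flagged, the run continues);
* ``analyze`` takes a trait CSV and writes the PCA report plus the
  spatio-temporal and environmental model-comparison tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from ovoscope import ecostats, eggsim, ovometry, radiometry, spotscan, uvalign

__all__ = ["RunConfig", "cmd_simulate", "cmd_measure", "cmd_analyze"]

log = logging.getLogger("ovoscope")

MEASURE_COLUMNS = [
    "egg_id", "status", "spot_number", "spot_size", "spottiness",
    "b_vis", "s_vis", "b_uv", "s_uv",
    "b_vis_R", "b_vis_G", "b_vis_B", "s_vis_R", "s_vis_G", "s_vis_B",
    "volume_mm3", "surface_mm2", "sv_per_mm", "mm_per_px",
    "roi_area_px", "spot_area_px",
]


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a pipeline run; unknown keys rejected."""

    seed: int
    input_dir: str = ""
    output_dir: str = "."
    n_eggs: int = 8
    gamma: float = 2.2
    noise_sd: float = 30.0
    standard_value: float = 40.0
    warp_style: str = "smooth_bumps"
    warp_magnitude_px: float = 4.0
    n_control_points: int = 16
    segmentation: dict = dataclasses.field(default_factory=dict)
    lwm_k_neighbors: int = 12
    n_stations: int = 200
    trait_csv: str = ""
    n_sites: int = 30
    eggs_per_site_mean: float = 110 / 30

    def __post_init__(self) -> None:
        if not 0 < self.standard_value <= 100:
            raise ValueError("standard_value must be in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, files: list[Path]) -> Path:
    manifest = {
        str(f.relative_to(outdir)): _sha256(f) for f in sorted(files)
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def _truth_sidecar(truth: eggsim.EggImageTruth) -> dict:
    return {
        "roi": truth.roi.tolist(),
        "standard_patch": truth.standard_patch.tolist(),
        "standard_patch_uv": truth.standard_patch_uv.tolist(),
        "standard_value": truth.standard_value,
        "scale_bar": truth.scale_bar.tolist(),
        "scale_bar_mm": truth.scale_bar_mm,
        "mm_per_px": truth.mm_per_px,
        "control_points_vis": truth.control_points_vis.tolist(),
        "control_points_uv": truth.control_points_uv.tolist(),
        "gamma": truth.gamma,
        "noise_sd": truth.noise_sd,
        "background_reflectance": truth.background_reflectance,
        "spot_reflectance": truth.spot_reflectance,
        "volume_mm3": truth.volume_mm3,
        "surface_mm2": truth.surface_mm2,
        "n_spots": int(len(truth.spot_circles)),
        "spottiness_truth": truth.spottiness_truth,
        "seed": truth.seed,
    }


def cmd_simulate(config: RunConfig, force: bool = False) -> Path:
    """Generate a deterministic fixture directory of egg image pairs."""
    outdir = Path(config.output_dir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    rng = np.random.default_rng(config.seed)
    for i in range(config.n_eggs):
        egg_seed = int(rng.integers(0, 2**31 - 1))
        truth = eggsim.make_egg_image(
            gamma=config.gamma,
            noise_sd=config.noise_sd,
            warp_params={
                "style": config.warp_style,
                "magnitude_px": config.warp_magnitude_px,
            },
            n_control_points=config.n_control_points,
            seed=egg_seed,
        )
        stem = outdir / f"egg{i:03d}"
        tifffile.imwrite(f"{stem}_vis.tif", truth.vis_raw)
        tifffile.imwrite(f"{stem}_uv.tif", truth.uv_raw)
        Path(f"{stem}_truth.json").write_text(
            json.dumps(_truth_sidecar(truth), indent=1)
        )
        files += [Path(f"{stem}_vis.tif"), Path(f"{stem}_uv.tif"),
                  Path(f"{stem}_truth.json")]
        log.info("simulated %s (seed %d)", stem.name, egg_seed)

    truth_tbl = eggsim.make_trait_dataset(
        n_sites=config.n_sites,
        eggs_per_site_mean=config.eggs_per_site_mean,
        seed=config.seed,
    )
    tpath = outdir / "traits_truth.csv"
    truth_tbl.table.to_csv(tpath, index=False)
    files.append(tpath)
    ppath = outdir / "trait_generator_params.json"
    ppath.write_text(json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in truth_tbl.params.items()}, indent=1))
    files.append(ppath)
    _write_manifest(outdir, files)
    return outdir


def measure_egg(
    vis_path: Path,
    uv_path: Path,
    sidecar: dict,
    config: RunConfig,
) -> dict:
    """Run the full image pipeline on one egg; returns one report row."""
    vis_raw = radiometry.RawImage(
        tifffile.imread(vis_path), ("R", "G", "B"), 16
    )
    uv_raw = radiometry.RawImage(tifffile.imread(uv_path), ("UV",), 16)
    gamma = float(sidecar.get("gamma", config.gamma))
    refl_vis = radiometry.to_reflectance(
        radiometry.linearize(vis_raw, gamma),
        np.asarray(sidecar["standard_patch"], float),
        config.standard_value,
    )
    refl_uv = radiometry.to_reflectance(
        radiometry.linearize(uv_raw, gamma),
        np.asarray(sidecar["standard_patch_uv"], float),
        config.standard_value,
    )
    roi = np.asarray(sidecar["roi"], float)
    mm_per_px = ovometry.calibrate_scale(
        np.asarray(sidecar["scale_bar"], float), sidecar["scale_bar_mm"]
    )
    seg = spotscan.SegmentationParams(**config.segmentation) \
        if config.segmentation else None
    mask = spotscan.segment_spots(refl_vis, roi, seg)
    report = spotscan.summarize(refl_vis, None, mask, roi, mm_per_px)

    row = {
        "spot_number": report.spot_number,
        "spot_size": report.spot_size,
        "spottiness": report.spottiness,
        "b_vis": report.b_vis,
        "s_vis": report.s_vis,
        "roi_area_px": report.roi_area_px,
        "spot_area_px": report.spot_area_px,
        "mm_per_px": mm_per_px,
    }
    for b in ("R", "G", "B"):
        row[f"b_vis_{b}"] = report.per_band_background.get(b, np.nan)
        row[f"s_vis_{b}"] = report.per_band_spot.get(b, np.nan)

    cps = uvalign.ControlPointSet(
        np.asarray(sidecar["control_points_vis"], float),
        np.asarray(sidecar["control_points_uv"], float),
    )
    transform = uvalign.fit_lwm(cps, config.lwm_k_neighbors)
    warped_mask = uvalign.warp_mask(mask.mask, transform, refl_uv.shape)
    roi_mask = radiometry.polygon_mask(roi, refl_vis.shape)
    warped_roi = uvalign.warp_mask(roi_mask, transform, refl_uv.shape)
    s_uv, b_uv = uvalign.uv_measure(refl_uv, warped_mask, warped_roi)
    row["s_uv"], row["b_uv"] = s_uv, b_uv

    profile = ovometry.extract_profile(roi, mm_per_px, config.n_stations)
    metrics = ovometry.volume_surface(profile)
    row.update(
        volume_mm3=metrics.volume_mm3,
        surface_mm2=metrics.surface_mm2,
        sv_per_mm=metrics.sv_per_mm,
    )
    return row


def cmd_measure(config: RunConfig) -> pd.DataFrame:
    """Measure every egg of a fixture directory into a flat CSV report."""
    indir = Path(config.input_dir)
    rows = []
    for vis_path in sorted(indir.glob("*_vis.tif")):
        egg_id = vis_path.name[: -len("_vis.tif")]
        uv_path = indir / f"{egg_id}_uv.tif"
        sc_path = indir / f"{egg_id}_truth.json"
        row: dict = {"egg_id": egg_id, "status": "ok"}
        try:
            if not uv_path.exists() or not sc_path.exists():
                raise FileNotFoundError("missing UV image or sidecar")
            sidecar = json.loads(sc_path.read_text())
            if len(sidecar.get("control_points_vis", [])) < \
                    uvalign.MIN_CONTROL_POINTS:
                # UV columns stay blank; VIS-side measurements still run
                sidecar_uvless = dict(sidecar)
                row.update(
                    measure_egg_visible_only(
                        vis_path, sidecar_uvless, config
                    )
                )
                row["status"] = "too_few_control_points"
            else:
                row.update(measure_egg(vis_path, uv_path, sidecar, config))
        except Exception as exc:  # noqa: BLE001 — row-flag and continue
            row["status"] = f"failed: {exc}"
            log.warning("egg %s failed: %s", egg_id, exc)
        rows.append(row)
    out = pd.DataFrame(rows, columns=MEASURE_COLUMNS)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.to_csv(outdir / "egg_report.csv", index=False)
    return out


def measure_egg_visible_only(
    vis_path: Path, sidecar: dict, config: RunConfig
) -> dict:
    """VIS-side measurements when UV alignment is impossible."""
    vis_raw = radiometry.RawImage(
        tifffile.imread(vis_path), ("R", "G", "B"), 16
    )
    gamma = float(sidecar.get("gamma", config.gamma))
    refl_vis = radiometry.to_reflectance(
        radiometry.linearize(vis_raw, gamma),
        np.asarray(sidecar["standard_patch"], float),
        config.standard_value,
    )
    roi = np.asarray(sidecar["roi"], float)
    mm_per_px = ovometry.calibrate_scale(
        np.asarray(sidecar["scale_bar"], float), sidecar["scale_bar_mm"]
    )
    mask = spotscan.segment_spots(refl_vis, roi)
    report = spotscan.summarize(refl_vis, None, mask, roi, mm_per_px)
    profile = ovometry.extract_profile(roi, mm_per_px, config.n_stations)
    metrics = ovometry.volume_surface(profile)
    return {
        "spot_number": report.spot_number,
        "spot_size": report.spot_size,
        "spottiness": report.spottiness,
        "b_vis": report.b_vis,
        "s_vis": report.s_vis,
        "mm_per_px": mm_per_px,
        "volume_mm3": metrics.volume_mm3,
        "surface_mm2": metrics.surface_mm2,
        "sv_per_mm": metrics.sv_per_mm,
    }


def cmd_analyze(config: RunConfig) -> dict:
    """PCA and model selection on a trait table CSV."""
    path = Path(config.trait_csv or Path(config.input_dir) /
                "traits_truth.csv")
    table = pd.read_csv(path)
    missing = [c for c in ecostats.REQUIRED_COVARIATES
               if c not in table.columns]
    if missing:
        raise KeyError(f"trait table lacks columns: {missing}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict = {}
    has_traits = all(c in table.columns for c in ecostats.TRAIT_ORDER)
    if has_traits:
        logged = ecostats.log_traits(table)
        pca = ecostats.pca_corr(logged)
        keep = ~logged["incomplete"].to_numpy(dtype=bool)
        table = table.loc[keep].reset_index(drop=True)
        table["pc1"] = pca.scores[:, 0]
        table["pc2"] = pca.scores[:, 1]
        pd.DataFrame(
            pca.loadings,
            index=list(ecostats.TRAIT_ORDER),
            columns=["pc1", "pc2"],
        ).to_csv(outdir / "pca_loadings.csv")
        results["pca"] = pca
    elif not {"pc1", "pc2"} <= set(table.columns):
        raise KeyError("trait table needs either the 7 traits or pc1/pc2")

    for response in ("pc1", "pc2"):
        sel = ecostats.run_selection(table, response)
        sel["spatio_temporal"].to_csv(
            outdir / f"{response}_spatio_temporal.csv"
        )
        sel["environmental"].to_csv(outdir / f"{response}_environmental.csv")
        (outdir / f"{response}_random_effect.json").write_text(
            json.dumps(sel["random_effect_assessment"], indent=1)
        )
        results[response] = sel
    return results
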