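"""End-to-end orchestration: simulate -> features -> PCA -> cross-validation.

One invocation owns one run directory.  For each of the six stages it
generates the phantom, simulates the projective image and the CT sinogram,
reconstructs a slice, samples ROIs, extracts the 20 x 9 feature matrix and
writes the per-specimen PCA report; it then assembles the 120-row staged
dataset and evaluates the 10-fold linear SVM.  A manifest records the full
configuration, every seed, library versions and every artifact path, so a
rerun with the identical configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from . import __version__
from .classify import build_dataset, tenfold_cv
from .config import RunConfig
from .errors import PipelineError
from .imaging import acquire_projection, acquire_sinogram, uniform_angles
from .io import read_json, save_projection, save_sinogram, write_json, write_tiff
from .pca import pca_report, pooled_component_sums
from .phantom import STAGE_ORDER, make_stage_volume
from .recon import fbp_reconstruct, neglog
from .texture import FEATURE_NAMES, feature_matrix, sample_rois, standard_offsets

logger = logging.getLogger(__name__)


def silhouette_mask(volume_wall_mask: np.ndarray, erosion_px: int = 0) -> np.ndarray:
    """Projected specimen silhouette: pixels whose beam path crosses the wall.

    ``erosion_px`` shrinks the silhouette so ROIs sample wall texture away
    from the steep intensity band at the organ border.
    """
    mask = volume_wall_mask.sum(axis=1) > 0
    if erosion_px:
        mask = binary_erosion(mask, iterations=int(erosion_px))
    return mask


def features_to_frame(fm: np.ndarray, rois, stage: str) -> pd.DataFrame:
    df = pd.DataFrame(fm, columns=list(FEATURE_NAMES))
    df.insert(0, "image_id", [r.image_id for r in rois])
    df.insert(1, "roi_row", [r.row for r in rois])
    df.insert(2, "roi_col", [r.col for r in rois])
    df["stage"] = stage
    return df


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    feature_paths = []
    fms_by_stage: dict[str, np.ndarray] = {}
    offsets = standard_offsets(cfg.glcm.distance)
    angles = uniform_angles(cfg.n_angles)

    for stage in STAGE_ORDER:
        try:
            spec = replace(cfg.stages[stage], seed=cfg.stages[stage].seed + cfg.seeds.phantom)
            vol = make_stage_volume(stage, cfg.grid_size, cfg.grid_height,
                                    spec=spec, cfg=cfg.physics, tissue=cfg.tissue)

            # Phantom record: central cross-section delta/beta + sidecar.
            central = vol.central_slice()
            for name, grid in (("delta", central.delta_grid), ("beta", central.beta_grid)):
                artifacts.append(str(write_tiff(
                    outdir / f"phantom_{stage.value}_{name}.tif", grid)))
            artifacts.append(str(write_json(
                outdir / f"phantom_{stage.value}.json",
                {"stage": stage.value, "seed": spec.seed,
                 "pixel_size": cfg.physics.pixel_size,
                 "spec": {"wall_thickness": spec.wall_thickness,
                          "roughness_amplitude": spec.roughness_amplitude,
                          "roughness_correlation_length": spec.roughness_correlation_length,
                          "nodule_count": spec.nodule_count,
                          "boundary_amplitude": spec.boundary_amplitude}})))

            ref = (0.0, cfg.ref_high_factor * cfg.physics.photon_count) \
                if cfg.quantization == "fixed" else None
            proj = acquire_projection(vol, 0.0, cfg.physics,
                                      seed=cfg.seeds.noise + stage.index,
                                      quantization=cfg.quantization,
                                      ref_range=ref, invert=cfg.invert_display)
            artifacts.extend(map(str, save_projection(
                proj, outdir / f"projection_{stage.value}")))

            sino = acquire_sinogram(vol, angles, cfg.physics,
                                    seed=cfg.seeds.noise + 100 + stage.index)
            artifacts.extend(map(str, save_sinogram(
                sino, outdir / f"sinogram_{stage.value}")))
            rec = fbp_reconstruct(neglog(sino, cfg.physics.photon_count))
            if rec.meta.get("neglog_floored"):
                logger.warning("stage %s: %d sinogram bins floored before -log",
                               stage.value, rec.meta["neglog_floored"])
            artifacts.append(str(write_tiff(
                outdir / f"slice_{stage.value}.tif", rec.data)))

            mask = silhouette_mask(vol.wall_mask, cfg.mask_erosion_px)
            rois = sample_rois(proj, mask, n=cfg.glcm.n_rois, size=cfg.glcm.roi_size,
                               seed=cfg.seeds.roi + stage.index)
            fm = feature_matrix(rois, levels=cfg.glcm.levels, offsets=offsets,
                                symmetric=cfg.glcm.symmetric)
            fms_by_stage[stage.value] = fm
            df = features_to_frame(fm, rois, stage.value)
            fpath = outdir / f"features_{stage.value}.csv"
            df.to_csv(fpath, index=False, float_format="%.10g")
            artifacts.append(str(fpath))
            feature_paths.append(fpath)

            report = pca_report(fm, ccr_threshold=cfg.pca.ccr_threshold,
                                score_threshold=cfg.pca.score_threshold,
                                score_mode=cfg.pca.score_mode,
                                sign_convention=cfg.pca.sign_convention)
            report["stage"] = stage.value
            artifacts.append(str(write_json(outdir / f"pca_{stage.value}.json", report)))
        except Exception as exc:
            raise PipelineError(f"stage '{stage.value}' failed in {outdir}: {exc}") from exc

    try:
        # Cross-stage comparison in one pooled component basis (per-specimen
        # eigenbases are mutually incomparable).
        pooled = pooled_component_sums(fms_by_stage,
                                       ccr_threshold=cfg.pca.ccr_threshold,
                                       sign_convention=cfg.pca.sign_convention)
        artifacts.append(str(write_json(outdir / "stage_comparison.json", pooled)))
    except Exception as exc:
        raise PipelineError(f"stage 'pooled-pca' failed in {outdir}: {exc}") from exc

    try:
        data = build_dataset(feature_paths, rows_per_stage=cfg.glcm.n_rois)
        cvrep = tenfold_cv(data, seed=cfg.seeds.cv, k=cfg.cv.k, C=cfg.cv.C)
        artifacts.append(str(write_json(outdir / "cv_report.json", cvrep.to_dict())))
        conf_path = outdir / "confusion.csv"
        cvrep.confusion.to_csv(conf_path)
        artifacts.append(str(conf_path))
    except Exception as exc:
        raise PipelineError(f"stage 'cv' failed in {outdir}: {exc}") from exc

    import numpy, scipy, skimage, sklearn  # noqa: PLC0415 — version stamp only
    write_json(outdir / "manifest.json", {
        "config": cfg.to_dict(),
        "artifacts": sorted(artifacts),
        "n_samples": int(data.n_samples),
        "versions": {"phasetex": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "scikit-image": skimage.__version__,
                     "scikit-learn": sklearn.__version__},
    })
    return outdir


def report_table(run_dir: str | Path) -> pd.DataFrame:
    """Summarize the per-stage PCA reports as one row per stage.

    Columns mirror the study's summary layout: F1 and F2 mean +- sd, their
    sum, the selected cumulative contribution rate and the region label.
    Missing stages yield a partial table with a warning; an empty run
    directory is an error.
    """
    run_dir = Path(run_dir)
    rows = []
    for stage in STAGE_ORDER:
        path = run_dir / f"pca_{stage.value}.json"
        if not path.exists():
            logger.warning("report_table: missing PCA report for stage %s", stage.value)
            continue
        rep = read_json(path)
        rows.append({
            "stage": stage.value,
            "F1": f"{rep['F1_mean']:.2f} ± {rep['F1_sd']:.2f}",
            "F2": f"{rep['F2_mean']:.2f} ± {rep['F2_sd']:.2f}",
            "F1+F2": f"{rep['sum_mean']:.2f} ± {rep['sum_sd']:.2f}",
            "CCR": f"{100 * rep['ccr_selected']:.2f}%",
            "n_components": rep["n_components"],
            "label": rep["label"],
        })
    if not rows:
        raise PipelineError(f"no PCA reports found in {run_dir}")
    return pd.DataFrame(rows)
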