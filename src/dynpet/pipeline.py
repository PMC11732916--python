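"""End-to-end orchestration: phantom (or files) -> IDIF -> sumSUV +
Patlak maps + VOI compartment fits -> contrast/report tables.

A run is fully described by a :class:`RunConfig`; with a fixed seed the
outputs are bit-reproducible.  Outputs land in one directory::

    manifest.json            config echo, seed, content hash
    idif.csv                 plasma curve and running integral
    sumsuv.nii.gz            late-window SUV map
    ki_<win>.nii.gz / dv_<win>.nii.gz   Patlak maps per window
    tcm_results.csv          per-VOI compartment fits
    table_contrast.csv       TBR/CNR mean +- SD per image type
    table_wilcoxon.csv       pairwise positive-rank counts and p-values
    table_params.csv         per-tissue parameter summary
    table_correlations.csv   Spearman rho of influx across methods
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio, metrics
from .errors import DynpetError
from .input_function import InputFunction, TimeActivityCurve, extract_idif
from .kinetics import FitSettings, fit_2tcm
from .patlak import patlak_fit, patlak_parametric_maps
from .synthetic import PhantomSpec, build_phantom

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageFailure", "run"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    phantom: PhantomSpec = None  # phantom source ...
    image_path: str = None  # ... or file source
    timing_path: str = None
    mask_path: str = None
    names_path: str = None
    windows: tuple = ("sti", "lti")
    weights: str = "uniform"
    fit_settings: FitSettings = field(default_factory=FitSettings)
    blood_name: str = "aorta"
    background_name: str = "liver"
    outdir: str = "dynpet_run"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "phantom": None if self.phantom is None else self.phantom.to_dict(),
            "image_path": self.image_path,
            "timing_path": self.timing_path,
            "mask_path": self.mask_path,
            "names_path": self.names_path,
            "windows": list(self.windows),
            "weights": self.weights,
            "fit_settings": {
                "max_iter": self.fit_settings.max_iter,
                "ftol": self.fit_settings.ftol,
                "init": self.fit_settings.init.as_dict(),
                "bounds_mode": self.fit_settings.bounds_mode,
                "k4_mode": self.fit_settings.k4_mode,
                "dt_s": self.fit_settings.dt_s,
            },
            "blood_name": self.blood_name,
            "background_name": self.background_name,
            "outdir": str(self.outdir),
            "seed": self.seed,
        }


class StageFailure(DynpetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, outdir, log):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.append({"stage": name, "seconds": round(dt, 3), "status": "ok"})
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            log.append({"stage": name, "seconds": round(dt, 3),
                        "status": f"error: {exc}"})
            (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
            raise StageFailure(name, exc) from exc

    return _Ctx()


def run(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns a result bundle.

    The bundle maps artefact names to in-memory objects (tables as
    DataFrames, maps as arrays) and every artefact is also written under
    ``config.outdir``.  Any stage error raises :class:`StageFailure`
    naming the stage, after persisting the log and partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    bundle: dict = {}

    with _stage("load_data", outdir, log):
        if config.phantom is not None:
            spec = config.phantom
            image, vois, truth = build_phantom(spec)
            truth.to_csv(outdir / "ground_truth.csv", index=False)
            bundle["truth"] = truth
        elif config.image_path is not None:
            image = dataio.read_dynamic(config.image_path, config.timing_path)
            vois = dataio.read_voiset(config.mask_path, config.names_path)
            if vois.label_map.shape != image.spatial_shape:
                raise DynpetError("mask grid does not match image grid")
        else:
            raise DynpetError("config must provide a phantom spec or input files")
        dataio.write_dynamic(image, outdir / "dynamic.nii.gz", outdir / "timing.csv")
        dataio.write_voiset(vois, outdir / "voi_mask.nii.gz", outdir / "voi_names.csv",
                            affine=image.affine)
    bundle["image"], bundle["vois"] = image, vois

    with _stage("input_function", outdir, log):
        idif_tac = extract_idif(image, vois, config.blood_name)
        input_fn = InputFunction(idif_tac)
        input_fn.to_frame().to_csv(outdir / "idif.csv", index=False)
    bundle["input_fn"] = input_fn

    with _stage("sumsuv", outdir, log):
        sumsuv = metrics.sum_suv(image)
        dataio.write_parametric_map(sumsuv, image, outdir / "sumsuv.nii.gz")
    bundle["sumsuv"] = sumsuv

    with _stage("patlak_maps", outdir, log):
        for win in config.windows:
            ki, dv, fitted = patlak_parametric_maps(
                image, input_fn, window=win, weights=config.weights
            )
            dataio.write_parametric_map(ki, image, outdir / f"ki_{win}.nii.gz")
            dataio.write_parametric_map(dv, image, outdir / f"dv_{win}.nii.gz")
            bundle[f"ki_{win}"] = ki
            bundle[f"dv_{win}"] = dv

    with _stage("voi_analysis", outdir, log):
        rows = []
        for label in vois.labels:
            name = vois.names[label]
            mask = vois.mask(label)
            tac = TimeActivityCurve(image.voxels[mask].mean(axis=0),
                                    image.schedule, source=name)
            row = {"name": name, "label": label,
                   "sumSUV": float(sumsuv[mask].mean())}
            for win in config.windows:
                pr = patlak_fit(tac, input_fn, window=win, weights=config.weights)
                row[f"patlak_ki_{win}"] = pr.ki
                row[f"patlak_dv_{win}"] = pr.dv
            if name != config.blood_name:
                fr = fit_2tcm(tac, input_fn, settings=config.fit_settings)
                row.update({
                    "tcm_vB": fr.params.vB, "tcm_K1": fr.params.K1,
                    "tcm_k2": fr.params.k2, "tcm_k3": fr.params.k3,
                    "tcm_ki": fr.ki, "tcm_chisq": fr.chisq,
                    "tcm_termination": fr.termination,
                })
            rows.append(row)
        voi_table = pd.DataFrame(rows)
        voi_table.to_csv(outdir / "tcm_results.csv", index=False)
    bundle["voi_table"] = voi_table

    with _stage("report", outdir, log):
        tables = build_report_tables(bundle, vois, config)
        for key, tbl in tables.items():
            tbl.to_csv(outdir / f"table_{key}.csv")
        bundle.update({f"table_{k}": v for k, v in tables.items()})

    with _stage("manifest", outdir, log):
        doc = config.to_dict()
        payload = json.dumps(doc, sort_keys=True).encode()
        manifest = {
            "config": doc,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(payload).hexdigest(),
            "stages": log,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    bundle["manifest"] = manifest
    return bundle


def _lesion_names(voi_table: pd.DataFrame) -> list:
    return [n for n in voi_table["name"] if n.startswith("tumor")]


def build_report_tables(bundle: dict, vois, config: RunConfig) -> dict:
    """Assemble the four report tables from a result bundle."""
    voi_table: pd.DataFrame = bundle["voi_table"]
    image = bundle["image"]
    background = config.background_name
    lesions = _lesion_names(voi_table)

    # image types: voxel maps keyed by name -> 3-D array
    maps = {"sumSUV": bundle["sumsuv"]}
    for win in config.windows:
        maps[f"{win.upper()} Ki"] = bundle[f"ki_{win}"]

    per_lesion: dict = {}
    for img_name, vol in maps.items():
        bg = metrics.voi_values(vol, vois, background)
        per_lesion[img_name] = {
            les: metrics.tbr_cnr(metrics.voi_values(vol, vois, les), bg)
            for les in lesions
        }
    # VOI-level compartment parameters: single value per VOI, TBR_mean only
    if "tcm_ki" in voi_table.columns:
        idx = voi_table.set_index("name")
        for col, img_name in (("tcm_ki", "2TCM Ki"), ("tcm_k3", "2TCM k3")):
            bg_val = float(idx.loc[background, col])
            per_lesion[img_name] = {
                les: metrics.tbr_cnr(float(idx.loc[les, col]), np.array([bg_val]))
                for les in lesions
            }

    contrast_rows = {}
    for img_name, by_lesion in per_lesion.items():
        frame = pd.DataFrame({les: m.as_dict() for les, m in by_lesion.items()}).T
        contrast_rows[img_name] = {
            f"{metric}_{stat}": val
            for metric in frame.columns
            for stat, val in (("mean", frame[metric].mean()),
                              ("sd", frame[metric].std(ddof=1)))
        }
    contrast = pd.DataFrame(contrast_rows).T
    contrast.index.name = "image_type"

    # pairwise Wilcoxon on lesion TBR_mean / CNR_mean
    wil_rows = []
    img_names = list(per_lesion)
    for a, b in itertools.combinations(img_names, 2):
        for metric in ("tbr_mean", "cnr_mean"):
            va = np.array([getattr(per_lesion[a][l], metric) for l in lesions])
            vb = np.array([getattr(per_lesion[b][l], metric) for l in lesions])
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() >= 5:
                count, p = metrics.wilcoxon_positive_ranks(va[ok], vb[ok])
            else:
                count, p = np.nan, np.nan
            wil_rows.append({"image_a": a, "image_b": b, "metric": metric,
                             "n": int(ok.sum()), "positive_ranks_a_gt_b": count,
                             "p_value": p})
    wilcoxon = pd.DataFrame(wil_rows).set_index(["image_a", "image_b", "metric"])

    # per-tissue parameter summary (phantom runs carry one VOI per tissue)
    params = voi_table.set_index("name")
    params.index.name = "tissue"

    # influx rank-correlation across methods, grouped tumor/normal
    ki_cols = {f"{w.upper()} Patlak Ki": f"patlak_ki_{w}" for w in config.windows}
    if "tcm_ki" in voi_table.columns:
        ki_cols["2TCM Ki"] = "tcm_ki"
    sub = voi_table[voi_table["name"] != config.blood_name]
    ki_frame = sub[list(ki_cols.values())].rename(
        columns={v: k for k, v in ki_cols.items()})
    groups = np.where(sub["name"].str.startswith("tumor"), "tumor", "normal")
    mats = metrics.rank_correlation_matrix(ki_frame, groups)
    corr = pd.concat(mats, names=["group", "method"])

    return {"contrast": contrast, "wilcoxon": wilcoxon,
            "params": params, "correlations": corr}
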