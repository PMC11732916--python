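"""Synthetic whole-body dynamic PET phantoms.

Generates 4-D dynamic volumes with the statistical structure the kinetic
analysis assumes: a Feng-type parametric arterial input, per-tissue
irreversible-2TCM time-activity curves built from a population-mean rate
constant library, the standard 33-frame/60-min schedule, and zero-mean
Gaussian noise whose variance scales with activity and inversely with
frame duration (a tractable surrogate for reconstruction noise).

The tissue library holds population-mean vB/K1/k2/k3 (k4 = 0) for liver,
kidney, spleen, lung, muscle, bone and a typical tumor lesion, so every
downstream stage can be validated by parameter recovery against known
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dataio import DynamicImage, VoiSet
from .errors import ParameterError, PhantomSpecError
from .input_function import FengInput, TimeActivityCurve
from .kinetics import KineticParams, forward_2tcm
from .schedule import FrameSchedule, standard_33frame_schedule

__all__ = [
    "default_tissue_library",
    "simulate_tac",
    "Region",
    "PhantomSpec",
    "default_phantom_spec",
    "build_phantom",
    "add_noise",
    "jittered_tissue_params",
    "multi_tissue_library",
]

#: population-mean rate constants per tissue (vB, K1, k2, k3), k4 = 0.
_TISSUE_TABLE = {
    "liver": (0.002, 0.571, 0.674, 0.005),
    "kidney": (0.066, 0.594, 0.428, 0.013),
    "spleen": (0.028, 1.478, 2.553, 0.010),
    "lung": (0.120, 0.014, 0.262, 0.159),
    "muscle": (0.0003, 0.051, 0.416, 0.015),
    "bone": (0.007, 0.248, 0.888, 0.028),
    "tumor": (0.057, 0.267, 0.863, 0.234),
}


#: population SDs matching :data:`_TISSUE_TABLE` (vB, K1, k2, k3)
_TISSUE_SD = {
    "liver": (0.017, 0.154, 0.185, 0.004),
    "kidney": (0.075, 0.427, 0.611, 0.034),
    "spleen": (0.045, 0.661, 1.087, 0.005),
    "lung": (0.053, 0.016, 0.250, 0.414),
    "muscle": (0.001, 0.031, 0.275, 0.005),
    "bone": (0.013, 0.108, 0.420, 0.009),
    "tumor": (0.090, 0.249, 0.809, 0.425),
}


def default_tissue_library() -> dict:
    """Ground-truth :class:`KineticParams` per tissue (k4 fixed at 0)."""
    return {
        name: KineticParams(vB=vB, K1=K1, k2=k2, k3=k3, k4=0.0)
        for name, (vB, K1, k2, k3) in _TISSUE_TABLE.items()
    }


def simulate_tac(params: KineticParams, input_model, schedule: FrameSchedule,
                 dt_s: float = 0.25, frame_average: bool = True) -> TimeActivityCurve:
    """Noiseless tissue TAC for one parameter set.

    Frame values are interval averages of the continuous model curve
    (matching scanner count binning); set ``frame_average=False`` for
    mid-point sampling.  This is the same forward solution used by the
    compartment fitter, evaluated on a finer grid.
    """
    params.validate_ground_truth()
    return forward_2tcm(params, input_model, schedule, dt_s=dt_s,
                        frame_average=frame_average)


def jittered_tissue_params(name: str, rng: np.random.Generator,
                           jitter: float = 1.0) -> KineticParams:
    """One inter-subject draw around a library tissue.

    Rate constants get multiplicative log-normal jitter whose coefficient
    of variation matches ``jitter`` times the population SD/mean ratio;
    ``vB`` gets additive Gaussian jitter clipped to [0, 1].
    """
    mean = np.array(_TISSUE_TABLE[name])
    sd = np.array(_TISSUE_SD[name]) * jitter
    vB = float(np.clip(mean[0] + rng.normal(0.0, sd[0]), 0.0, 1.0))
    rates = []
    for m, s in zip(mean[1:], sd[1:]):
        if m <= 0 or s == 0:
            rates.append(m)
            continue
        sigma = np.sqrt(np.log1p((s / m) ** 2))
        rates.append(m * np.exp(rng.normal(-0.5 * sigma**2, sigma)))
    return KineticParams(vB=vB, K1=rates[0], k2=rates[1], k3=rates[2], k4=0.0)


def multi_tissue_library(n_regions: int, seed: int = 0, jitter: float = 1.0,
                         tumor_fraction: float = 0.4) -> list:
    """Jittered parameter sets for a many-region phantom.

    Returns ``[(region_name, tissue_type, KineticParams), ...]`` with
    ``round(n_regions * tumor_fraction)`` tumor-typed regions and the
    remainder cycling through the normal organs.
    """
    rng = np.random.default_rng(seed)
    n_tumor = int(round(n_regions * tumor_fraction))
    normals = [t for t in _TISSUE_TABLE if t != "tumor"]
    out = []
    for i in range(n_tumor):
        out.append((f"tumor_{i+1}", "tumor",
                    jittered_tissue_params("tumor", rng, jitter)))
    for i in range(n_regions - n_tumor):
        base = normals[i % len(normals)]
        out.append((f"{base}_{i+1}", "normal",
                    jittered_tissue_params(base, rng, jitter)))
    return out


@dataclass
class Region:
    """One geometric tissue region of a phantom."""

    name: str
    label: int
    shape: str  # "ellipsoid" | "box"
    center: tuple  # voxel coordinates
    radii: tuple  # voxel half-extents per axis
    params: KineticParams = None  # None => blood pool (carries Cp)
    tissue_type: str = "normal"  # "normal" | "tumor" | "blood"

    def voxel_mask(self, grid_shape) -> np.ndarray:
        coords = np.indices(grid_shape, dtype=float)
        c = np.asarray(self.center, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if self.shape == "ellipsoid":
            d = sum(((coords[i] - c[i]) / r[i]) ** 2 for i in range(3))
            return d <= 1.0
        if self.shape == "box":
            return np.all(
                [np.abs(coords[i] - c[i]) <= r[i] for i in range(3)], axis=0
            )
        raise PhantomSpecError(f"unknown region shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Full description of a synthetic dynamic-PET study."""

    grid_shape: tuple = (48, 48, 96)
    voxel_size: tuple = (1.65, 1.65, 1.65)
    regions: list = field(default_factory=list)
    input_model: FengInput = field(default_factory=FengInput)
    schedule: FrameSchedule = field(default_factory=standard_33frame_schedule)
    noise_model: str = "duration_scaled_gaussian"
    noise_scale: float = 0.3
    noise_floor: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size": list(self.voxel_size),
            "regions": [
                {
                    "name": r.name, "label": r.label, "shape": r.shape,
                    "center": list(r.center), "radii": list(r.radii),
                    "tissue_type": r.tissue_type,
                    "params": None if r.params is None else r.params.as_dict(),
                }
                for r in self.regions
            ],
            "input_model": self.input_model.parameters(),
            "schedule": {
                "starts_s": self.schedule.starts.tolist(),
                "durations_s": self.schedule.durations.tolist(),
            },
            "noise_model": self.noise_model,
            "noise_scale": self.noise_scale,
            "noise_floor": self.noise_floor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PhantomSpec":
        regions = []
        for r in doc.get("regions", []):
            p = r.get("params")
            params = None
            if p is not None:
                params = KineticParams(
                    vB=p["vB"], K1=p["K1"], k2=p["k2"], k3=p["k3"],
                    k4=p.get("k4", 0.0),
                )
            regions.append(Region(
                name=r["name"], label=int(r["label"]), shape=r["shape"],
                center=tuple(r["center"]), radii=tuple(r["radii"]),
                params=params, tissue_type=r.get("tissue_type", "normal"),
            ))
        fi = doc.get("input_model", {})
        sched_doc = doc.get("schedule")
        schedule = (
            FrameSchedule(sched_doc["starts_s"], sched_doc["durations_s"])
            if sched_doc else standard_33frame_schedule()
        )
        return cls(
            grid_shape=tuple(doc.get("grid_shape", (48, 48, 96))),
            voxel_size=tuple(doc.get("voxel_size", (1.65, 1.65, 1.65))),
            regions=regions,
            input_model=FengInput(**fi),
            schedule=schedule,
            noise_model=doc.get("noise_model", "duration_scaled_gaussian"),
            noise_scale=float(doc.get("noise_scale", 0.3)),
            noise_floor=float(doc.get("noise_floor", 0.01)),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "PhantomSpec":
        text = open(path).read()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(doc)


def default_phantom_spec(noise_scale: float = 0.3, seed: int = 0,
                         grid_shape=(48, 48, 96)) -> PhantomSpec:
    """The reference phantom: seven organs, a descending-aorta blood pool
    and three tumor lesions on a small grid sized for voxel-wise fitting
    in minutes."""
    lib = default_tissue_library()
    sx, sy, sz = grid_shape
    f = np.array([sx / 48.0, sy / 48.0, sz / 96.0])

    def sc(center, radii):
        return tuple(np.round(np.asarray(center) * f, 1)), tuple(
            np.maximum(np.round(np.asarray(radii) * f, 1), 1.0)
        )

    layout = [
        ("aorta", "ellipsoid", (24, 11, 48), (3.5, 3.5, 42), None, "blood"),
        ("liver", "ellipsoid", (13, 28, 26), (11, 13, 20), lib["liver"], "normal"),
        ("kidney", "ellipsoid", (36, 30, 24), (6, 6, 9), lib["kidney"], "normal"),
        ("spleen", "ellipsoid", (37, 14, 28), (5, 6, 8), lib["spleen"], "normal"),
        ("lung", "ellipsoid", (13, 26, 74), (10, 12, 17), lib["lung"], "normal"),
        ("muscle", "ellipsoid", (38, 38, 76), (8, 8, 16), lib["muscle"], "normal"),
        ("bone", "ellipsoid", (24, 40, 48), (4, 5, 30), lib["bone"], "normal"),
        ("tumor_1", "ellipsoid", (36, 12, 60), (4, 4, 4), lib["tumor"], "tumor"),
        ("tumor_2", "ellipsoid", (10, 10, 52), (3, 3, 3), lib["tumor"], "tumor"),
        ("tumor_3", "ellipsoid", (38, 24, 70), (3, 3, 3), lib["tumor"], "tumor"),
        ("tumor_4", "ellipsoid", (8, 40, 8), (2.5, 2.5, 2.5), lib["tumor"], "tumor"),
        ("tumor_5", "ellipsoid", (40, 40, 40), (3, 3, 3), lib["tumor"], "tumor"),
        ("tumor_6", "ellipsoid", (8, 8, 82), (2.5, 2.5, 2.5), lib["tumor"], "tumor"),
    ]
    regions = []
    for i, (name, shape, center, radii, params, ttype) in enumerate(layout, start=1):
        center, radii = sc(center, radii)
        regions.append(Region(name=name, label=i, shape=shape, center=center,
                              radii=radii, params=params, tissue_type=ttype))
    return PhantomSpec(grid_shape=tuple(grid_shape), regions=regions,
                       noise_scale=noise_scale, seed=seed)


def build_phantom(spec: PhantomSpec):
    """Voxelise a phantom spec into a dynamic image, VOI set and truth table.

    Every voxel of a region carries that region's noiseless TAC (blood
    regions carry the frame-averaged input curve); noise is then added
    according to the spec.  Returns ``(DynamicImage, VoiSet, DataFrame)``
    where the truth table lists each region's generating parameters and
    derived influx.
    """
    label_map = np.zeros(spec.grid_shape, dtype=np.int16)
    names = {}
    masks = {}
    for region in spec.regions:
        m = region.voxel_mask(spec.grid_shape)
        if not m.any():
            raise PhantomSpecError(f"region {region.name!r} contains no voxels")
        if (label_map[m] != 0).any():
            raise PhantomSpecError(f"region {region.name!r} overlaps another region")
        label_map[m] = region.label
        names[region.label] = region.name
        masks[region.label] = m

    n_frames = spec.schedule.n_frames
    voxels = np.zeros(spec.grid_shape + (n_frames,), dtype=float)
    cp_frames = spec.input_model.frame_averages(spec.schedule)
    truth_rows = []
    for region in spec.regions:
        if region.params is None:
            tac = cp_frames
            prm = KineticParams(vB=1.0, K1=0.0, k2=0.0, k3=0.0)
        else:
            tac = simulate_tac(region.params, spec.input_model, spec.schedule).values
            prm = region.params
        voxels[masks[region.label]] = tac
        truth_rows.append({
            "name": region.name, "label": region.label,
            "tissue_type": region.tissue_type,
            "n_voxels": int(masks[region.label].sum()),
            **prm.as_dict(),
        })

    image = DynamicImage(voxels, spec.schedule, spec.voxel_size)
    if spec.noise_scale > 0:
        image = add_noise(image, model=spec.noise_model, scale=spec.noise_scale,
                          seed=spec.seed, floor=spec.noise_floor)
    vois = VoiSet(label_map, names)
    truth = pd.DataFrame(truth_rows)
    return image, vois, truth


def add_noise(image: DynamicImage, model: str = "duration_scaled_gaussian",
              scale: float = 0.3, seed: int = 0, floor: float = 0.01) -> DynamicImage:
    """Zero-mean Gaussian noise with variance ``scale * max(v, floor) / dur_min``.

    The variance grows with local activity and shrinks with frame
    duration, the leading-order behaviour of count-limited PET
    reconstruction noise.  ``scale = 0`` is the identity.
    """
    if scale < 0:
        raise ParameterError("noise scale must be >= 0")
    if model != "duration_scaled_gaussian":
        raise ParameterError(f"unknown noise model {model!r}")
    if scale == 0:
        return image
    rng = np.random.default_rng(seed)
    dur = image.schedule.durations_min
    sd = np.sqrt(scale * np.maximum(image.voxels, floor) / dur)
    noisy = image.voxels + rng.standard_normal(image.voxels.shape) * sd
    return DynamicImage(noisy, image.schedule, image.voxel_size, image.affine)
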