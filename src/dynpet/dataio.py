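"""Reading and writing the standard formats of the pipeline.

Dynamic volumes, VOI label maps and parametric maps are NIfTI-1 files
(via nibabel); frame timing travels in a CSV or JSON sidecar with
columns ``frame,start_s,duration_s``; VOI names in a two-column CSV
``label,name``.  All dynamic data are handled in SUV (body-weight
normalised, decay-corrected); masks must share the image grid exactly —
this module never resamples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, NamingError, ScheduleError
from .schedule import FrameSchedule

__all__ = [
    "DynamicImage",
    "VoiSet",
    "read_dynamic",
    "write_dynamic",
    "read_timing",
    "write_timing",
    "read_voiset",
    "write_voiset",
    "write_parametric_map",
    "read_parametric_map",
]

logger = logging.getLogger(__name__)

_DEFAULT_VOXEL_MM = (1.65, 1.65, 1.65)


@dataclass
class DynamicImage:
    """4-D dynamic PET volume in SUV units bound to its frame schedule.

    Attributes
    ----------
    voxels : ndarray, shape (x, y, z, t)
        SUV values; the 4th axis length equals ``schedule.n_frames``.
    schedule : FrameSchedule
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray (4, 4)
        NIfTI voxel-to-world (RAS+) transform.
    """

    voxels: np.ndarray
    schedule: FrameSchedule
    voxel_size: tuple = _DEFAULT_VOXEL_MM
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise FormatError(f"dynamic image must be 4-D, got {self.voxels.ndim}-D")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise FormatError(
                f"frame axis length {self.voxels.shape[3]} does not match "
                f"schedule with {self.schedule.n_frames} frames"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise FormatError("voxel_size entries must all be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("dynamic image contains non-finite values")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def spatial_shape(self) -> tuple:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames


@dataclass
class VoiSet:
    """Labelled 3-D VOI mask aligned to a dynamic image grid.

    Label 0 is reserved for "outside all VOIs".  ``names`` maps every
    non-zero label occurring in the map to a tissue name.
    """

    label_map: np.ndarray
    names: dict

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 3:
            raise FormatError("label map must be 3-D")
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise FormatError("label map must hold integer labels")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        if 0 in self.names:
            raise NamingError("label 0 is reserved for background-outside-VOIs")
        present = set(int(v) for v in np.unique(self.label_map)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise NamingError(f"labels without a name: {sorted(unnamed)}")
        missing = set(self.names) - present
        if missing:
            raise NamingError(f"named labels absent from map: {sorted(missing)}")
        if not present:
            warnings.warn("VOI mask is empty: no named regions", stacklevel=2)

    @property
    def labels(self) -> list:
        return sorted(self.names)

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise NamingError(f"no VOI named {name!r}")

    def mask(self, label_or_name) -> np.ndarray:
        """Boolean mask for one VOI, by integer label or by name."""
        lab = (
            self.label_of(label_or_name)
            if isinstance(label_or_name, str)
            else int(label_or_name)
        )
        return self.label_map == lab


# ---------------------------------------------------------------------------
# timing sidecars


def read_timing(path) -> FrameSchedule:
    """Read a frame-timing sidecar (CSV ``frame,start_s,duration_s`` or the
    JSON dialect ``{"frame_starts_s": [...], "frame_durations_s": [...]}``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        try:
            starts = doc["frame_starts_s"]
            durations = doc["frame_durations_s"]
        except KeyError as exc:
            raise FormatError(f"timing JSON missing key: {exc}") from exc
    else:
        table = pd.read_csv(path)
        required = {"frame", "start_s", "duration_s"}
        if not required.issubset(table.columns):
            raise FormatError(
                f"timing CSV must have columns {sorted(required)}, got {list(table.columns)}"
            )
        table = table.sort_values("frame")
        starts = table["start_s"].to_numpy()
        durations = table["duration_s"].to_numpy()
    return FrameSchedule(starts, durations)


def write_timing(schedule: FrameSchedule, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "frame_starts_s": schedule.starts.tolist(),
            "frame_durations_s": schedule.durations.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        pd.DataFrame(
            {
                "frame": np.arange(1, schedule.n_frames + 1),
                "start_s": schedule.starts,
                "duration_s": schedule.durations,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dynamic volumes


def read_dynamic(image_path, timing_path) -> DynamicImage:
    """Load a 4-D NIfTI dynamic volume and its timing sidecar.

    Fails (rather than truncating) when the sidecar row count does not
    match the frame axis.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D dynamic NIfTI, got {data.ndim}-D")
    schedule = read_timing(timing_path)
    if data.shape[3] != schedule.n_frames:
        raise ScheduleError(
            f"image has {data.shape[3]} frames but sidecar describes {schedule.n_frames}"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(data, schedule, tuple(float(z) for z in zooms), np.asarray(img.affine))


def write_dynamic(image: DynamicImage, image_path, timing_path=None) -> None:
    nii = nib.Nifti1Image(image.voxels.astype(np.float64), image.affine)
    nii.header.set_zooms(tuple(image.voxel_size) + (1.0,))
    nib.save(nii, str(image_path))
    if timing_path is not None:
        write_timing(image.schedule, timing_path)


# ---------------------------------------------------------------------------
# VOI masks


def read_voiset(mask_path, names_path) -> VoiSet:
    """Load an integer NIfTI label map plus its ``label,name`` CSV."""
    img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"VOI mask must be 3-D, got {data.ndim}-D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise FormatError("VOI mask voxels are not integer-valued")
        data = rounded.astype(np.int32)
    table = pd.read_csv(names_path)
    if not {"label", "name"}.issubset(table.columns):
        raise FormatError("names table must have columns label,name")
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    present = set(int(v) for v in np.unique(data)) - {0}
    # only names for labels actually present are kept; extra rows tolerated
    names = {k: v for k, v in names.items() if k in present}
    if present - set(names):
        raise NamingError(f"mask labels without a name: {sorted(present - set(names))}")
    return VoiSet(data, names)


def write_voiset(vois: VoiSet, mask_path, names_path, affine=None) -> None:
    if affine is None:
        affine = np.diag(list(_DEFAULT_VOXEL_MM) + [1.0])
    nib.save(nib.Nifti1Image(vois.label_map.astype(np.int16), affine), str(mask_path))
    pd.DataFrame(
        {"label": vois.labels, "name": [vois.names[k] for k in vois.labels]}
    ).to_csv(names_path, index=False)


# ---------------------------------------------------------------------------
# parametric maps


def write_parametric_map(volume, reference, path) -> None:
    """Write a 3-D parametric map on the grid of ``reference``.

    Parameters
    ----------
    volume : ndarray (x, y, z)
        Map values; NaN marks voxels where the fit failed.
    reference : DynamicImage or ndarray (4, 4)
        Either the dynamic image whose grid the map shares, or an affine.
    path : path-like
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise FormatError(f"parametric map must be 3-D, got {volume.ndim}-D")
    if isinstance(reference, DynamicImage):
        if volume.shape != reference.spatial_shape:
            raise FormatError(
                f"map shape {volume.shape} does not match image grid {reference.spatial_shape}"
            )
        affine = reference.affine
    else:
        affine = np.asarray(reference, dtype=float)
    nib.save(nib.Nifti1Image(volume, affine), str(path))


def read_parametric_map(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"parametric map must be 3-D, got {data.ndim}-D")
    return data
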