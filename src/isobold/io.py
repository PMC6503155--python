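"""Shared grid/event containers and file I/O.

Volumes are NIfTI-1 (via nibabel), event tables are tab-separated text in
the BIDS events dialect (``onset`` and ``duration`` are the first two
columns, in seconds from session start, 0-based). All voxel coordinates in
this package are 0-based indices; world coordinates, where needed, go
through the image affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Volume4D",
    "Parcellation",
    "TrialEvent",
    "EventTable",
    "SubjectDataset",
    "FormatError",
    "read_bold",
    "write_bold",
    "read_parcellation",
    "write_parcellation",
    "read_events",
    "write_events",
    "read_motion",
    "write_motion",
    "smooth_gaussian",
]

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_id",
    "session",
    "modality",
    "physical_level",
    "rating",
    "rating_onset",
    "rating_duration",
]

MODALITIES = ("pain", "tactile")
PHYSICAL_LEVELS = ("low", "high")


class FormatError(ValueError):
    """A file or record did not satisfy the format contract."""


@dataclass
class Volume4D:
    """A 4-D BOLD grid: ``data[x, y, z, t]`` in arbitrary signal units.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
    tr : float
        Seconds per volume (repetition time).
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    mask : ndarray of bool, shape (X, Y, Z), optional
        In-brain voxels; defaults to all-true.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world transform; defaults to a scaled identity.
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4-D image, got {self.data.ndim}-D")
        if self.data.shape[3] < 1:
            raise FormatError("time axis must have at least 1 volume")
        if not self.tr > 0:
            raise FormatError(f"tr must be positive, got {self.tr}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise FormatError(
                    f"mask shape {self.mask.shape} does not match spatial "
                    f"shape {self.data.shape[:3]}"
                )
        if not np.all(np.isfinite(self.data[self.mask])):
            raise FormatError("non-finite voxels inside mask")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    def masked_timeseries(self) -> np.ndarray:
        """Return the in-mask data as a (T, V) matrix (V in mask order)."""
        return self.data[self.mask].T


@dataclass
class Parcellation:
    """Integer region labels on the spatial grid; 0 is background."""

    labels: np.ndarray
    region_ids: tuple[int, ...] = ()
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("parcellation labels must be integers")
        if self.labels.ndim != 3:
            raise FormatError("parcellation must be a 3-D label volume")
        present = np.unique(self.labels)
        present = tuple(int(v) for v in present if v != 0)
        if any(v < 0 for v in present):
            raise FormatError("negative region label")
        if not self.region_ids:
            self.region_ids = present
        else:
            self.region_ids = tuple(int(r) for r in self.region_ids)
            extra = set(present) - set(self.region_ids)
            if extra:
                raise FormatError(f"labels contain ids not in region_ids: {sorted(extra)}")

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def region_sizes(self) -> dict[int, int]:
        return {r: int(np.sum(self.labels == r)) for r in self.region_ids}


@dataclass
class TrialEvent:
    """One stimulus trial: modality, timing and the perceived-intensity rating r."""

    trial_id: str
    session: int
    modality: str
    physical_level: str
    stim_onset_s: float
    rating: float
    rating_onset_s: float
    rating_duration_s: float = 10.0
    duration_s: float = 0.0
    # analysis label slots, filled by trial_matching
    matched: bool | None = None
    pair_id: str | None = None
    split: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not 0.0 <= self.rating <= 10.0:
            raise FormatError(f"rating {self.rating} outside [0, 10]")
        if not self.rating_onset_s > self.stim_onset_s:
            raise FormatError("rating_onset_s must follow stim_onset_s")


class EventTable:
    """Ordered list of :class:`TrialEvent` with per-trial label slots."""

    def __init__(self, events: Sequence[TrialEvent]):
        events = sorted(events, key=lambda e: (e.session, e.stim_onset_s))
        ids = [e.trial_id for e in events]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate trial_id(s): {dup}")
        self.events: list[TrialEvent] = list(events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.events == other.events

    def by_modality(self, modality: str) -> list[TrialEvent]:
        return [e for e in self.events if e.modality == modality]

    def session_events(self, session: int) -> list[TrialEvent]:
        return [e for e in self.events if e.session == session]

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(sorted({e.session for e in self.events}))

    def copy(self) -> "EventTable":
        return EventTable([replace(e) for e in self.events])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "onset": e.stim_onset_s,
                    "duration": e.duration_s,
                    "trial_id": e.trial_id,
                    "session": e.session,
                    "modality": e.modality,
                    "physical_level": e.physical_level,
                    "rating": e.rating,
                    "rating_onset": e.rating_onset_s,
                    "rating_duration": e.rating_duration_s,
                    "matched": "" if e.matched is None else str(int(e.matched)),
                    "pair_id": "" if e.pair_id is None else e.pair_id,
                    "split": "" if e.split is None else e.split,
                }
            )
        return pd.DataFrame(rows, columns=EVENT_COLUMNS + ["matched", "pair_id", "split"])


@dataclass
class SubjectDataset:
    """One subject: per-session BOLD, one event table, per-session motion."""

    bold: dict[int, Volume4D]
    events: EventTable
    motion: dict[int, np.ndarray]
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        shapes = {v.shape[:3] for v in self.bold.values()}
        trs = {v.tr for v in self.bold.values()}
        if len(shapes) > 1 or len(trs) > 1:
            raise FormatError("sessions must share grid shape and tr")
        for ses, vol in self.bold.items():
            mot = np.asarray(self.motion[ses], dtype=float)
            if mot.shape != (vol.n_scans, 6):
                raise FormatError(
                    f"session {ses}: motion shape {mot.shape} != ({vol.n_scans}, 6)"
                )
            self.motion[ses] = mot

    @property
    def tr(self) -> float:
        return next(iter(self.bold.values())).tr


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_bold(path: str | Path) -> Volume4D:
    """Read a 4-D NIfTI BOLD image; TR is taken from the 4th pixdim."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected 4-D image, got {data.ndim}-D: {path}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if not tr > 0:
        raise FormatError(f"non-positive tr ({tr}) in header: {path}")
    return Volume4D(
        data=np.asarray(data, dtype=np.float64),
        tr=tr,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine),
    )


def write_bold(vol: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (vol.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_parcellation(path: str | Path) -> Parcellation:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3-D label image, got {data.ndim}-D: {path}")
    labels = np.rint(data).astype(np.int32)
    return Parcellation(labels=labels, affine=np.asarray(img.affine))


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    affine = parc.affine if parc.affine is not None else np.eye(4)
    img = nib.Nifti1Image(parc.labels.astype(np.int32), affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Event and motion tables


def read_events(path: str | Path) -> EventTable:
    """Read a tab-separated events file (BIDS dialect, see EVENT_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str}, keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    events = []
    for i, row in df.iterrows():
        try:
            ev = TrialEvent(
                trial_id=str(row["trial_id"]),
                session=int(row["session"]),
                modality=str(row["modality"]),
                physical_level=str(row["physical_level"]),
                stim_onset_s=float(row["onset"]),
                duration_s=float(row["duration"]),
                rating=float(row["rating"]),
                rating_onset_s=float(row["rating_onset"]),
                rating_duration_s=float(row["rating_duration"]),
                matched=(bool(int(row["matched"])) if str(row.get("matched", "")) != "" else None),
                pair_id=(str(row["pair_id"]) if str(row.get("pair_id", "")) != "" else None),
                split=(str(row["split"]) if str(row.get("split", "")) != "" else None),
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"row {i + 1}: {exc}") from exc
        events.append(ev)
    return EventTable(events)


def write_events(table: EventTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_motion(path: str | Path) -> np.ndarray:
    mot = pd.read_csv(path, sep="\t", header=None,
                      float_precision="round_trip").to_numpy(dtype=float)
    if mot.ndim != 2 or mot.shape[1] != 6:
        raise FormatError(f"motion table must have 6 columns, got shape {mot.shape}")
    return mot


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(motion, dtype=float)).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Smoothing


def smooth_gaussian(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Spatially smooth each volume with an isotropic Gaussian of given FWHM.

    sigma = fwhm / sqrt(8 ln 2) in mm, converted per axis via the voxel size.
    Reflective boundary handling keeps constant images constant.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return Volume4D(
            data=vol.data.copy(),
            tr=vol.tr,
            voxel_size=vol.voxel_size,
            mask=vol.mask.copy(),
            affine=vol.affine,
        )
    sigma_mm = fwhm_mm / np.sqrt(8.0 * np.log(2.0))
    sigma_vox = [sigma_mm / vs for vs in vol.voxel_size] + [0.0]
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="reflect")
    return Volume4D(
        data=smoothed,
        tr=vol.tr,
        voxel_size=vol.voxel_size,
        mask=vol.mask.copy(),
        affine=vol.affine,
    )
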