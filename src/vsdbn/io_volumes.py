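"""Volume and mask I/O: NIfTI reading/writing and time-by-voxel matrix assembly.

The whole pipeline works on 2D matrices whose rows are fMRI volumes (one per
TR) and whose columns are in-mask voxels.  A :class:`BrainMask` fixes a
deterministic bijection between in-mask 3D coordinates and column indices so
that spatial maps produced anywhere downstream can always be folded back into
3D brain space.  Multi-subject data are concatenated along time into a single
group matrix of shape ``(v * n, m)`` (``v`` TRs per subject, ``n`` subjects,
``m`` voxels); the volume-as-sample layout used for training is simply this
matrix with rows as samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import nibabel as nib
import numpy as np

logger = logging.getLogger("vsdbn")

__all__ = [
    "BrainMask",
    "DataMatrix",
    "load_subject",
    "intersect_masks",
    "normalize_columns",
    "build_group_matrix",
    "maps_to_nifti",
    "save_matrix_h5",
    "load_matrix_h5",
]


class DimensionError(ValueError):
    """Shapes of volumes, masks, or matrices do not agree."""


class InvalidMaskError(ValueError):
    """Mask contains no voxels (or otherwise cannot index a volume)."""


@dataclass(frozen=True)
class BrainMask:
    """Boolean 3D mask with a fixed linear ordering of in-mask voxels.

    The ordering is row-major (C order, last axis fastest) over the 3D grid,
    restricted to in-mask voxels.  This is the ordering ``numpy`` uses for
    ``array[mask]``, so masking and un-masking are mutually inverse by
    construction.
    """

    inside: np.ndarray  # 3D boolean

    def __post_init__(self):
        inside = np.asarray(self.inside, dtype=bool)
        if inside.ndim != 3:
            raise DimensionError(f"mask must be 3D, got shape {inside.shape}")
        object.__setattr__(self, "inside", inside)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.inside.shape

    @property
    def m(self) -> int:
        """Number of in-mask voxels."""
        return int(self.inside.sum())

    def coordinates(self) -> np.ndarray:
        """(m, 3) integer coordinates of in-mask voxels, in column order."""
        return np.argwhere(self.inside)

    def unmask(self, values: np.ndarray) -> np.ndarray:
        """Fold a length-m vector (or q x m matrix) back into 3D (or 4D) space."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.m:
            raise DimensionError(
                f"expected {self.m} values per map, got {values.shape[1]}"
            )
        out = np.zeros((values.shape[0],) + self.shape, dtype=float)
        out[:, self.inside] = values
        return out[0] if out.shape[0] == 1 else out

    @classmethod
    def from_nifti(cls, path) -> "BrainMask":
        img = nib.load(str(path))
        return cls(inside=np.asarray(img.dataobj) > 0)

    def to_nifti(self, path, affine=None) -> str:
        affine = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.inside.astype(np.uint8), affine), str(path))
        return str(path)


@dataclass
class DataMatrix:
    """Time-by-voxel data matrix tied to a :class:`BrainMask`.

    ``values[t, j]`` is the signal of voxel ``j`` (in mask column order) at
    TR ``t``.  For a group matrix, ``segments`` records the half-open row
    ranges belonging to each subject, in concatenation order.
    """

    values: np.ndarray
    mask: BrainMask
    subject_id: str = "subject"
    tr_seconds: float = 1.5
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    dropped_columns: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("DataMatrix values must be 2D (time x voxels)")
        if self.values.shape[1] != self.mask.m:
            raise DimensionError(
                f"matrix has {self.values.shape[1]} columns but mask has "
                f"{self.mask.m} in-mask voxels"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def get_segment(self, subject_id: str) -> np.ndarray:
        for start, stop, sid in self.segments:
            if sid == subject_id:
                return self.values[start:stop]
        raise KeyError(f"no segment for subject {subject_id!r}")


def load_subject(volume_file, mask: BrainMask, subject_id: str = "subject",
                 tr_seconds: float = 1.5) -> DataMatrix:
    """Extract the in-mask voxel time series of one 4D NIfTI volume.

    Returns a matrix with one row per TR and one column per in-mask voxel,
    columns ordered by the mask's deterministic voxel order.
    """
    img = nib.load(str(volume_file))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionError(f"expected 4D volume, got {data.ndim}D")
    if data.shape[:3] != mask.shape:
        raise DimensionError(
            f"volume grid {data.shape[:3]} does not match mask {mask.shape}"
        )
    if mask.m == 0:
        raise InvalidMaskError("mask contains no voxels")
    # (x, y, z, t) -> (t, m) in mask column order
    values = data[mask.inside, :].T
    return DataMatrix(values=values, mask=mask, subject_id=subject_id,
                      tr_seconds=tr_seconds)


def intersect_masks(masks: list[BrainMask]) -> BrainMask:
    """Group-wise common mask: voxel kept iff inside every input mask."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for mk in masks[1:]:
        if mk.shape != shape:
            raise DimensionError(f"mask shapes differ: {mk.shape} vs {shape}")
    inside = np.logical_and.reduce([mk.inside for mk in masks])
    return BrainMask(inside=inside)


def normalize_columns(dm: DataMatrix, tol: float = 1e-12) -> DataMatrix:
    """Z-score every voxel time series to zero mean and unit variance.

    Uses the population standard deviation (divide by the number of TRs), so
    the operation is idempotent.  Zero-variance voxels cannot be z-scored;
    they are dropped from both the matrix and the mask, with their column
    indices recorded in ``dropped_columns`` and a logged warning.
    """
    x = dm.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population sd
    constant = sd <= tol
    if constant.any():
        idx = np.flatnonzero(constant)
        warnings.warn(
            f"dropping {idx.size} constant voxel column(s): {idx.tolist()[:10]}"
            f"{'...' if idx.size > 10 else ''}", stacklevel=2)
        logger.warning("normalize_columns: dropped %d constant columns", idx.size)
        coords = dm.mask.coordinates()[idx]
        new_inside = dm.mask.inside.copy()
        new_inside[tuple(coords.T)] = False
        new_mask = BrainMask(inside=new_inside)
        keep = ~constant
        values = (x[:, keep] - mean[keep]) / sd[keep]
        return replace(dm, values=values, mask=new_mask, dropped_columns=idx)
    values = (x - mean) / sd
    return replace(dm, values=values, dropped_columns=np.array([], dtype=int))


def build_group_matrix(subjects: list[DataMatrix]) -> DataMatrix:
    """Concatenate subject matrices along time into the group matrix.

    For ``n`` subjects of ``v`` TRs each the result has ``v * n`` rows and the
    shared ``m`` columns; each subject's half-open row range is recorded as a
    segment in input order.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    m = subjects[0].m
    mask = subjects[0].mask
    for s in subjects[1:]:
        if s.m != m or s.mask.shape != mask.shape or not np.array_equal(
                s.mask.inside, mask.inside):
            raise DimensionError("subjects must share one mask")
    segments, start = [], 0
    for s in subjects:
        segments.append((start, start + s.n_timepoints, s.subject_id))
        start += s.n_timepoints
    values = np.vstack([s.values for s in subjects])
    return DataMatrix(values=values, mask=mask, subject_id="group",
                      tr_seconds=subjects[0].tr_seconds, segments=segments)


def maps_to_nifti(maps: np.ndarray, mask: BrainMask, path, affine=None) -> str:
    """Write a stack of spatial maps as a 4D NIfTI, zeros outside the mask.

    ``maps`` is (q, m): one row per map.  The 4th NIfTI axis indexes maps.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[1] != mask.m:
        raise DimensionError(
            f"maps have {maps.shape[1]} voxels but mask has {mask.m}")
    vols = np.zeros(mask.shape + (maps.shape[0],), dtype=np.float32)
    vols[mask.inside, :] = maps.T
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vols, affine), str(path))
    return str(path)


def save_matrix_h5(dm: DataMatrix, path) -> str:
    """Serialize a DataMatrix (values + mask + segments) to HDF5."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("values", data=dm.values, track_times=False)
        f.create_dataset("mask", data=dm.mask.inside.astype(np.uint8), track_times=False)
        f.attrs["subject_id"] = dm.subject_id
        f.attrs["tr_seconds"] = dm.tr_seconds
        if dm.segments:
            f.create_dataset(
                "segment_bounds",
                data=np.array([[a, b] for a, b, _ in dm.segments]), track_times=False)
            f.attrs["segment_ids"] = [sid for _, _, sid in dm.segments]
    return str(path)


def load_matrix_h5(path) -> DataMatrix:
    with h5py.File(str(path), "r") as f:
        mask = BrainMask(inside=f["mask"][...].astype(bool))
        segments = []
        if "segment_bounds" in f:
            bounds = f["segment_bounds"][...]
            ids = list(f.attrs["segment_ids"])
            segments = [(int(a), int(b), str(sid))
                        for (a, b), sid in zip(bounds, ids)]
        return DataMatrix(values=f["values"][...], mask=mask,
                          subject_id=str(f.attrs["subject_id"]),
                          tr_seconds=float(f.attrs["tr_seconds"]),
                          segments=segments)
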