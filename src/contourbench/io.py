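"""Cohort data model and NIfTI mask I/O.

Every downstream stage (metrics, consensus fusion, bootstrap experiments)
consumes the canonical :class:`BinaryMask` / :class:`ObserverContour`
representation defined here.  Masks are 3D boolean voxel grids with
anisotropic physical spacing; observers are tagged ``expert`` or
``nonexpert`` and grouped per (case, ROI).

Conventions
-----------
* Axis order is (slice, row, column); voxel indices are 0-based.
* The physical coordinate of voxel index ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (element-wise) and refers to the voxel
  center.
* NIfTI affines must be axis-aligned: diagonal up to sign.  Negative
  diagonal entries (flips) are honoured by flipping the data array and
  shifting the origin; any other rotation raises, rather than silently
  resampling.
* All masks of one (case, ROI) must share grid shape, spacing and origin;
  no resampling is ever performed.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

logger = logging.getLogger("contourbench")

__all__ = [
    "BinaryMask",
    "Expertise",
    "ObserverContour",
    "CohortManifest",
    "Cohort",
    "AmbiguousLabelError",
    "NonAxisAlignedError",
    "CohortValidationError",
    "read_mask",
    "write_mask",
    "load_cohort",
]

SPACING_ATOL_MM = 1e-4
ORIGIN_ATOL_MM = 1e-3


class AmbiguousLabelError(ValueError):
    """A mask file contains more than one distinct nonzero label."""


class NonAxisAlignedError(ValueError):
    """A NIfTI affine contains rotation beyond axis-aligned flips."""


class CohortValidationError(ValueError):
    """A cohort manifest fails grid-compatibility or uniqueness checks."""


class Expertise(str, Enum):
    EXPERT = "expert"
    NONEXPERT = "nonexpert"


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean segmentation mask on a regular anisotropic grid.

    Parameters
    ----------
    voxels
        Boolean array with axes (slice, row, column).
    spacing
        Physical voxel size in mm per axis, all components > 0.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={vox.ndim}")
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("voxels must contain only {0, 1}")
            vox = vox.astype(bool)
        object.__setattr__(self, "voxels", vox)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must have 3 components")
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def indices_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to physical mm coordinates."""
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(
            self.origin
        )

    def grid_compatible(self, other: "BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=SPACING_ATOL_MM, rtol=0)
            and np.allclose(self.origin, other.origin, atol=ORIGIN_ATOL_MM, rtol=0)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.voxels, other.voxels)
            and self.spacing == other.spacing
            and self.origin == other.origin
        )


def require_grid_compatible(*masks: BinaryMask) -> None:
    ref = masks[0]
    for m in masks[1:]:
        if not ref.grid_compatible(m):
            raise ValueError(
                "grid mismatch: shapes "
                f"{ref.shape} vs {m.shape}, spacing {ref.spacing} vs {m.spacing}, "
                f"origin {ref.origin} vs {m.origin}"
            )


@dataclass(frozen=True)
class ObserverContour:
    """One observer's mask for one (case, ROI)."""

    observer_id: str
    expertise: Expertise
    case_id: str
    roi_name: str
    mask: BinaryMask

    def __post_init__(self) -> None:
        object.__setattr__(self, "expertise", Expertise(self.expertise))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.observer_id, self.case_id, self.roi_name)


@dataclass
class CohortManifest:
    """Parsed manifest rows: (case_id, roi_name, observer_id, expertise, path)."""

    entries: list[tuple[str, str, str, Expertise, Path]] = field(default_factory=list)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"case_id", "roi_name", "observer_id", "expertise", "path"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise CohortValidationError(
                    f"manifest must have columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                mask_path = Path(row["path"])
                if not mask_path.is_absolute():
                    mask_path = path.parent / mask_path
                entries.append(
                    (
                        row["case_id"],
                        row["roi_name"],
                        row["observer_id"],
                        Expertise(row["expertise"]),
                        mask_path,
                    )
                )
        return cls(entries=entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "roi_name", "observer_id", "expertise", "path"])
            for case_id, roi, obs, exp, p in self.entries:
                writer.writerow([case_id, roi, obs, exp.value, str(p)])


class Cohort:
    """Observer contours grouped by (case_id, roi_name).

    Iteration order over groups and over observers within a group is
    deterministic (sorted), independent of manifest row order.
    """

    def __init__(self, contours: Iterable[ObserverContour]):
        self._by_group: dict[tuple[str, str], list[ObserverContour]] = {}
        seen: dict[tuple[str, str, str], ObserverContour] = {}
        expertise_by_obs_case: dict[tuple[str, str], Expertise] = {}
        for c in contours:
            if c.key in seen:
                raise CohortValidationError(
                    f"duplicate (observer, case, roi) key: {c.key}"
                )
            seen[c.key] = c
            prior = expertise_by_obs_case.setdefault(
                (c.observer_id, c.case_id), c.expertise
            )
            if prior != c.expertise:
                raise CohortValidationError(
                    f"observer {c.observer_id!r} has conflicting expertise for "
                    f"case {c.case_id!r}: {prior.value} vs {c.expertise.value}"
                )
            self._by_group.setdefault((c.case_id, c.roi_name), []).append(c)
        for key, group in self._by_group.items():
            group.sort(key=lambda c: c.observer_id)
            ref = group[0]
            for c in group[1:]:
                if not ref.mask.grid_compatible(c.mask):
                    raise CohortValidationError(
                        f"grid mismatch in ({key[0]}, {key[1]}): observer "
                        f"{c.observer_id!r} disagrees with {ref.observer_id!r}"
                    )

    def groups(self) -> list[tuple[str, str]]:
        return sorted(self._by_group)

    def contours(self, case_id: str, roi_name: str) -> list[ObserverContour]:
        return list(self._by_group[(case_id, roi_name)])

    def by_expertise(
        self, case_id: str, roi_name: str, expertise: Expertise | str
    ) -> list[ObserverContour]:
        expertise = Expertise(expertise)
        return [
            c
            for c in self._by_group[(case_id, roi_name)]
            if c.expertise == expertise
        ]

    def group_counts(self, case_id: str, roi_name: str) -> tuple[int, int]:
        """(n_experts, n_nonexperts) present for one (case, ROI)."""
        group = self._by_group[(case_id, roi_name)]
        n_exp = sum(1 for c in group if c.expertise == Expertise.EXPERT)
        return n_exp, len(group) - n_exp

    def __len__(self) -> int:
        return sum(len(g) for g in self._by_group.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.groups() != other.groups():
            return False
        for key in self.groups():
            a, b = self._by_group[key], other._by_group[key]
            if len(a) != len(b) or any(x != y for x, y in zip(a, b)):
                return False
        return True


def _axis_aligned_geometry(
    affine: np.ndarray, shape: tuple[int, ...]
) -> tuple[np.ndarray | None, tuple[float, ...], tuple[float, ...]]:
    """Decompose an affine into (flip axes, spacing, origin).

    The rotation block must be diagonal up to sign; axis permutations and
    oblique rotations are rejected.  Returns the list of axes to flip so the
    stored array matches the increasing-coordinate convention.
    """
    rot = affine[:3, :3]
    diag = np.diag(rot)
    off = rot - np.diag(diag)
    if np.any(np.abs(off) > 1e-6 * max(1.0, np.abs(diag).max())):
        raise NonAxisAlignedError(
            "affine has off-diagonal rotation components; only axis-aligned "
            f"grids (with flips) are supported:\n{rot}"
        )
    spacing = np.abs(diag)
    if np.any(spacing <= 0):
        raise NonAxisAlignedError(f"affine has zero scale on some axis: {diag}")
    origin = affine[:3, 3].astype(float).copy()
    flip_axes = [int(ax) for ax in range(3) if diag[ax] < 0]
    for ax in flip_axes:
        # after flipping the array, voxel 0 sits at the other end
        origin[ax] = origin[ax] + diag[ax] * (shape[ax] - 1)
    return (np.array(flip_axes, dtype=int) if flip_axes else None), tuple(
        float(s) for s in spacing
    ), tuple(float(o) for o in origin)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI volume as a :class:`BinaryMask`.

    Nonzero voxels map to foreground.  A file with more than one distinct
    nonzero label is ambiguous and rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    labels = np.unique(data)
    nonzero = labels[labels != 0]
    if len(nonzero) > 1:
        raise AmbiguousLabelError(
            f"{path}: more than one nonzero label present: {nonzero.tolist()}"
        )
    flips, spacing, origin = _axis_aligned_geometry(img.affine, data.shape)
    vox = data != 0
    if flips is not None:
        vox = np.flip(vox, axis=tuple(flips.tolist()))
    return BinaryMask(np.ascontiguousarray(vox), spacing, origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a {0,1}-valued NIfTI volume with its geometry."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = mask.spacing
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_data_dtype(np.uint8)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path}: {exc}") from exc


def load_cohort(manifest_path: str | Path, verbose: bool = False) -> Cohort:
    """Load all contours referenced by a manifest CSV and validate the cohort.

    Logs expert/nonexpert counts per (case, ROI) to stderr when ``verbose``.
    """
    manifest = CohortManifest.from_csv(manifest_path)
    contours = []
    for case_id, roi, obs, exp, mask_path in manifest.entries:
        if not Path(mask_path).exists():
            raise CohortValidationError(
                f"manifest references missing file: {mask_path} "
                f"(observer {obs!r}, {case_id}/{roi})"
            )
        contours.append(
            ObserverContour(
                observer_id=obs,
                expertise=exp,
                case_id=case_id,
                roi_name=roi,
                mask=read_mask(mask_path),
            )
        )
    cohort = Cohort(contours)
    if verbose:
        if not logger.handlers:
            logger.addHandler(logging.StreamHandler(sys.stderr))
        logger.setLevel(logging.INFO)
        for case_id, roi in cohort.groups():
            n_exp, n_non = cohort.group_counts(case_id, roi)
            logger.info(
                "%s/%s: %d experts, %d nonexperts", case_id, roi, n_exp, n_non
            )
    return cohort
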