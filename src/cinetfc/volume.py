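"""The central image container: a 4D cine label volume.

Short-axis cine CMR segmentations are stored as an integer grid indexed
``(phase, slice, row, col)`` with labels 0 = background, 1 = LV blood pool,
2 = RV blood pool.  Slice 0 is the most apical slice and the last slice the
most basal one; physical voxel size is carried alongside the grid so that
voxel counts convert to millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND = 0
LV = 1
RV = 2

STRUCTURE_LABELS = {"LV": LV, "RV": RV}


def structure_label(structure: int | str) -> int:
    """Map a structure name ("LV"/"RV") or label integer to the label integer."""
    if isinstance(structure, str):
        try:
            return STRUCTURE_LABELS[structure.upper()]
        except KeyError:
            raise ValueError(f"unknown structure {structure!r}") from None
    if structure not in (LV, RV):
        raise ValueError(f"structure label must be {LV} (LV) or {RV} (RV), got {structure}")
    return int(structure)


@dataclass
class CineLabelVolume:
    """4D cine segmentation with physical spacing.

    Parameters
    ----------
    labels
        Integer array of shape ``(n_phases, n_slices, n_rows, n_cols)`` with
        values in {0, 1, 2}.
    in_plane_spacing_mm
        Row and column voxel size in millimetres.
    slice_thickness_mm
        Through-plane voxel size in millimetres.
    """

    labels: np.ndarray
    in_plane_spacing_mm: tuple[float, float] = (1.25, 1.25)
    slice_thickness_mm: float = 8.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise ValueError(f"labels must be 4D (phase, slice, row, col), got {self.labels.ndim}D")
        if not np.isin(self.labels, (BACKGROUND, LV, RV)).all():
            raise ValueError("labels must take values in {0, 1, 2}")
        sp = (*self.in_plane_spacing_mm, self.slice_thickness_mm)
        if any(s <= 0 for s in sp):
            raise ValueError(f"voxel spacing must be positive, got {sp}")

    @property
    def n_phases(self) -> int:
        return self.labels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.labels.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape[2:]

    @property
    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in millilitres (mm^3 / 1000)."""
        dy, dx = self.in_plane_spacing_mm
        return dy * dx * self.slice_thickness_mm / 1000.0

    def same_grid(self, other: "CineLabelVolume") -> bool:
        return (
            self.labels.shape == other.labels.shape
            and np.allclose(self.in_plane_spacing_mm, other.in_plane_spacing_mm)
            and np.isclose(self.slice_thickness_mm, other.slice_thickness_mm)
        )

    def structure_mask(self, structure: int | str, phase: int | None = None) -> np.ndarray:
        lab = structure_label(structure)
        arr = self.labels if phase is None else self.labels[phase]
        return arr == lab

    def copy(self, name: str | None = None) -> "CineLabelVolume":
        return CineLabelVolume(
            self.labels.copy(),
            tuple(self.in_plane_spacing_mm),
            self.slice_thickness_mm,
            self.name if name is None else name,
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        """Write as 4D NIfTI with spacing in the header zooms.

        The on-disk axis order is the NIfTI-conventional (col, row, slice,
        phase); :meth:`from_nifti` restores the in-memory order.
        """
        data = np.transpose(self.labels.astype(np.uint8), (3, 2, 1, 0))
        dy, dx = self.in_plane_spacing_mm
        affine = np.diag([dx, dy, self.slice_thickness_mm, 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((dx, dy, self.slice_thickness_mm, 1.0))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CineLabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim == 3:  # single phase stored 3D
            data = data[..., np.newaxis]
        labels = np.transpose(data, (3, 2, 1, 0)).astype(np.uint8)
        dx, dy, dz = img.header.get_zooms()[:3]
        return cls(labels, (float(dy), float(dx)), float(dz), name=Path(path).stem)
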