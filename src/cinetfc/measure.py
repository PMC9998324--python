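"""Clinical measurements from cine label volumes.

Voxel-count volumetry per cardiac phase, automatic end-diastole /
end-systole phase selection (ED = phase of maximal segmented volume, ES =
phase of minimal volume), EDV/ESV/SV/EF with body-surface-area indexing,
and the simulated expert correction that replaces the automatic
segmentation of the most basal slice with the manual reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .volume import BACKGROUND, CineLabelVolume, structure_label

__all__ = [
    "VolumeCurve",
    "StructureMeasurements",
    "MeasurementSet",
    "normalize_intensities",
    "compute_volume",
    "volume_curve",
    "select_phases",
    "basal_slice_index",
    "apply_basal_correction",
    "compute_measurements",
    "bsa_mosteller",
    "bsa_dubois",
]


@dataclass
class VolumeCurve:
    """Per-phase volume (ml) of one ventricle."""

    structure: str
    volumes_ml: np.ndarray

    def __post_init__(self) -> None:
        structure_label(self.structure)
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if self.volumes_ml.ndim != 1:
            raise ValueError("volumes_ml must be a 1D sequence")
        if (self.volumes_ml < 0).any():
            raise ValueError("volumes must be non-negative")

    @property
    def n_phases(self) -> int:
        return len(self.volumes_ml)


@dataclass
class StructureMeasurements:
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_percent: float
    edvi_ml_per_m2: float
    esvi_ml_per_m2: float
    ed_phase: int
    es_phase: int


@dataclass
class MeasurementSet:
    """EDV/ESV/SV/EF and BSA-indexed volumes for both ventricles."""

    lv: StructureMeasurements
    rv: StructureMeasurements
    bsa_m2: float

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"bsa_m2": self.bsa_m2}
        for name, m in (("lv", self.lv), ("rv", self.rv)):
            for k, v in asdict(m).items():
                row[f"{name}_{k}"] = v
        return row


# --------------------------------------------------------------------------
def normalize_intensities(image: np.ndarray) -> np.ndarray:
    """Rescale a scan to [0, 1] on its 1st–99th intensity percentiles.

    Values below the 1st percentile clamp to 0 and above the 99th to 1; a
    constant image maps to all zeros (with a warning).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    p1, p99 = np.percentile(image, (1, 99))
    if p99 <= p1:
        warnings.warn("constant image: percentile normalization degenerate, "
                      "returning zeros")
        return np.zeros_like(image)
    return np.clip((image - p1) / (p99 - p1), 0.0, 1.0)


def compute_volume(labelvol: CineLabelVolume, phase: int,
                   structure: int | str) -> float:
    """Voxel-count volume (ml) of one structure at one phase."""
    if not (0 <= phase < labelvol.n_phases):
        raise IndexError(f"phase {phase} out of range [0, {labelvol.n_phases})")
    n = int(labelvol.structure_mask(structure, phase).sum())
    return n * labelvol.voxel_volume_ml


def volume_curve(labelvol: CineLabelVolume, structure: int | str) -> VolumeCurve:
    """Volume of one structure at every phase of the cycle."""
    lab = structure_label(structure)
    counts = (labelvol.labels == lab).sum(axis=(1, 2, 3))
    name = "LV" if lab == 1 else "RV"
    return VolumeCurve(name, counts * labelvol.voxel_volume_ml)


def select_phases(curve: VolumeCurve | np.ndarray) -> tuple[int, int]:
    """ED/ES phase indices: ED at the volume maximum, ES at the minimum.

    Ties break to the earliest phase index.  An all-zero curve signals an
    empty segmentation and raises.
    """
    v = curve.volumes_ml if isinstance(curve, VolumeCurve) else np.asarray(curve, float)
    if v.size == 0:
        raise ValueError("empty volume curve")
    if not v.any():
        raise ValueError("all-zero volume curve: structure never segmented")
    return int(v.argmax()), int(v.argmin())


def basal_slice_index(labelvol: CineLabelVolume, phase: int,
                      scope: str = "volume",
                      structure: int | str | None = None,
                      other: CineLabelVolume | None = None) -> int:
    """Index of the most basal (highest) slice containing ventricular label.

    ``scope="volume"`` (default) looks at the union of LV and RV — and of
    ``labelvol`` with ``other`` when given, so that reference and automatic
    segmentations share one basal slice.  ``scope="structure"`` restricts to
    one ventricle of ``labelvol``.
    """
    if scope not in ("volume", "structure"):
        raise ValueError("scope must be 'volume' or 'structure'")
    if scope == "structure":
        if structure is None:
            raise ValueError("scope='structure' requires a structure")
        mask = labelvol.structure_mask(structure, phase)
    else:
        mask = labelvol.labels[phase] != BACKGROUND
        if other is not None:
            mask = mask | (other.labels[phase] != BACKGROUND)
    slices = np.flatnonzero(mask.any(axis=(1, 2)))
    if slices.size == 0:
        raise ValueError(f"no foreground voxels at phase {phase}")
    return int(slices[-1])


def apply_basal_correction(auto: CineLabelVolume, reference: CineLabelVolume,
                           phases: tuple[int, ...] | None = None) -> CineLabelVolume:
    """Simulated expert correction: replace the most basal slice of the
    automatic segmentation with the corresponding manual reference slice.

    The basal slice is located per phase on the union of both segmentations
    and both structures; all other voxels are untouched.  ``phases=None``
    corrects every phase.
    """
    if not auto.same_grid(reference):
        raise ValueError("automatic and reference volumes are on different grids")
    if phases is None:
        phases = tuple(range(auto.n_phases))
    out = auto.copy(name=f"{auto.name}-basal" if auto.name else "automatic-basal")
    for ph in phases:
        k = basal_slice_index(auto, ph, scope="volume", other=reference)
        out.labels[ph, k] = reference.labels[ph, k]
    return out


def compute_measurements(labelvol: CineLabelVolume, bsa_m2: float,
                         per_structure_phases: bool = True) -> MeasurementSet:
    """Full volumetric/functional measurement set for both ventricles.

    ED and ES are selected per ventricle independently by default; with
    ``per_structure_phases=False`` a single volume-wide phase pair (from the
    summed LV+RV curve) is used for both.
    """
    if bsa_m2 <= 0:
        raise ValueError("bsa_m2 must be positive")
    curves = {name: volume_curve(labelvol, name) for name in ("LV", "RV")}
    if not per_structure_phases:
        total = curves["LV"].volumes_ml + curves["RV"].volumes_ml
        shared = select_phases(VolumeCurve("LV", total))
    out = {}
    for name, curve in curves.items():
        ed, es = select_phases(curve) if per_structure_phases else shared
        edv, esv = float(curve.volumes_ml[ed]), float(curve.volumes_ml[es])
        if edv <= 0:
            raise ValueError(f"{name} EDV is zero: ejection fraction undefined")
        sv = edv - esv
        out[name] = StructureMeasurements(
            edv_ml=edv, esv_ml=esv, sv_ml=sv, ef_percent=100.0 * sv / edv,
            edvi_ml_per_m2=edv / bsa_m2, esvi_ml_per_m2=esv / bsa_m2,
            ed_phase=ed, es_phase=es,
        )
    return MeasurementSet(lv=out["LV"], rv=out["RV"], bsa_m2=bsa_m2)


# --------------------------------------------------------------------------
def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area: sqrt(height·weight/3600), in m²."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """DuBois–DuBois body surface area: 0.007184·h^0.725·w^0.425, in m²."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425
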