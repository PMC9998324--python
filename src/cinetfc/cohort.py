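"""Synthetic cine-CMR cohort generator.

Builds reproducible cohorts of subjects under evaluation for arrhythmogenic
right ventricular cardiomyopathy (ARVC): demographics, a ground-truth
("manual reference") 4D cine label volume per subject, and a degraded
("automatic-like") segmentation whose errors concentrate in the most basal
slice — the dominant failure mode of automatic short-axis segmentation.

Three groups are simulated: controls, at-risk family members, and ARVC
patients, with group-dependent RV dilation (higher RVEDVI), RV dysfunction
(lower RVEF) and regional wall-motion abnormality prevalence.  The phantom
anatomy is deliberately crude — LV as a disc, RV as an adjacent crescent,
both tapering toward the apex — but carries exact voxel-counted volumes, so
every downstream measurement can be validated against generator truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, LV, RV, CineLabelVolume, structure_label

__all__ = [
    "Subject",
    "GroupParams",
    "CohortConfig",
    "DegradationSpec",
    "GeneratorTruth",
    "CohortRecord",
    "volume_profile",
    "rasterize_phantom",
    "generate_cohort",
    "iter_cohort",
    "degrade_segmentation",
    "render_image",
    "largest_remainder",
    "write_cohort",
]

GROUPS = ("control", "at_risk", "arvc")

# Slice-location error allocation of automatic short-axis segmentation,
# fractions over (basal, mid-ventricular, apical, outside the base/apex).
DEFAULT_RV_ALLOCATION = (0.307, 0.61, 0.054, 0.029)
DEFAULT_LV_ALLOCATION = (0.183, 0.70, 0.075, 0.042)


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------
@dataclass
class Subject:
    """Demographic and clinical record of one simulated subject."""

    id: str
    sex: str  # "male" | "female"
    age_years: float
    group: str  # "control" | "at_risk" | "arvc"
    bsa_m2: float
    rwma: bool  # regional RV wall-motion abnormality present
    noncmr_points: int  # summed points of the five non-CMR TFC categories

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.bsa_m2 <= 0:
            raise ValueError("bsa_m2 must be positive")
        if not (0 <= self.noncmr_points <= 10):
            raise ValueError("noncmr_points must lie in [0, 10]")


@dataclass
class GroupParams:
    """Per-group distribution parameters (means and SDs of indexed volumes
    in ml/m^2 and ejection fractions in %)."""

    rvedvi: tuple[float, float]
    rvef: tuple[float, float]
    lvedvi: tuple[float, float]
    lvef: tuple[float, float]
    rwma_probability: float
    # discrete distribution of summed non-CMR TFC points: (values, probs)
    noncmr_points: tuple[tuple[int, ...], tuple[float, ...]]


def _default_group_params() -> dict[str, GroupParams]:
    # Plausible group separations: ARVC patients show RV dilation, reduced
    # RVEF and frequent wall-motion abnormality; at-risk family members are
    # near-normal; controls are normal.  Chosen so that roughly 84% of ARVC
    # subjects and ~3% of at-risk subjects meet a minor/major CMR criterion.
    return {
        "control": GroupParams(
            rvedvi=(76.0, 10.0), rvef=(58.0, 5.0),
            lvedvi=(80.0, 10.0), lvef=(60.0, 5.0),
            rwma_probability=0.02,
            noncmr_points=((0, 1), (0.8, 0.2)),
        ),
        "at_risk": GroupParams(
            rvedvi=(80.0, 10.0), rvef=(54.0, 5.0),
            lvedvi=(82.0, 10.0), lvef=(58.0, 5.0),
            rwma_probability=0.15,
            noncmr_points=((0, 1, 2, 3), (0.2, 0.4, 0.3, 0.1)),
        ),
        "arvc": GroupParams(
            rvedvi=(108.0, 16.0), rvef=(38.0, 7.0),
            lvedvi=(88.0, 12.0), lvef=(52.0, 6.0),
            rwma_probability=0.90,
            noncmr_points=((2, 3, 4, 5), (0.2, 0.4, 0.3, 0.1)),
        ),
    }


@dataclass
class CohortConfig:
    """Everything needed to draw a cohort deterministically."""

    n_subjects: int = 157
    # Exact test-cohort composition (controls, at-risk, ARVC); the rounded
    # percentages are 34/42/24.
    group_proportions: tuple[float, float, float] = (54 / 157, 66 / 157, 37 / 157)
    group_params: dict[str, GroupParams] = field(default_factory=_default_group_params)
    female_fraction: float = 0.59
    age_mean_sd: tuple[float, float] = (36.9, 17.6)
    bsa_mean_sd: tuple[float, float] = (1.9, 0.2)
    grid_shape: tuple[int, int] = (160, 160)
    n_slices: int = 12
    in_plane_spacing_range_mm: tuple[float, float] = (1.11, 1.45)
    slice_thickness_range_mm: tuple[float, float] = (7.0, 10.0)
    n_phases_range: tuple[int, int] = (25, 40)
    es_fraction_mean_sd: tuple[float, float] = (0.38, 0.03)
    exact_proportions: bool = True  # largest-remainder sizing vs multinomial draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        p = np.asarray(self.group_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must be a 3-vector of non-negative "
                             "values summing to 1")
        for g, gp in self.group_params.items():
            for nm in ("rvedvi", "rvef", "lvedvi", "lvef"):
                mean, sd = getattr(gp, nm)
                if sd < 0:
                    raise ValueError(f"{g}.{nm} SD must be non-negative")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=list))


@dataclass
class DegradationSpec:
    """How to corrupt a reference segmentation into an "automatic-like" one.

    ``error_fraction`` of the structure's foreground voxels (per perturbed
    phase) are flipped; the flips are spread over four slice locations —
    most basal, mid-ventricular, most apical, and slices outside the
    structure's extent — according to ``slice_allocation``.
    """

    structure: str = "RV"
    error_fraction: float = 0.05
    slice_allocation: tuple[float, float, float, float] | None = None
    deletion_fraction: float = 0.5  # share of flips that delete vs add voxels
    all_phases: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        structure_label(self.structure)
        if not (0.0 <= self.error_fraction <= 1.0):
            raise ValueError("error_fraction must lie in [0, 1]")
        if not (0.0 <= self.deletion_fraction <= 1.0):
            raise ValueError("deletion_fraction must lie in [0, 1]")
        if self.slice_allocation is None:
            self.slice_allocation = (
                DEFAULT_RV_ALLOCATION if self.structure.upper() == "RV"
                else DEFAULT_LV_ALLOCATION
            )
        a = np.asarray(self.slice_allocation, dtype=float)
        if a.shape != (4,) or (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("slice_allocation must be 4 non-negative values summing to 1")


@dataclass
class GeneratorTruth:
    """Ground truth the generator knows about one subject's heart."""

    ed_phase: int
    es_phase: int
    lv_edv_ml: float
    lv_esv_ml: float
    rv_edv_ml: float
    rv_esv_ml: float
    lv_curve_ml: np.ndarray
    rv_curve_ml: np.ndarray


@dataclass
class CohortRecord:
    subject: Subject
    reference: CineLabelVolume
    truth: GeneratorTruth


# --------------------------------------------------------------------------
# cardiac-cycle volume profile
# --------------------------------------------------------------------------
def volume_profile(edv_ml: float, esv_ml: float, n_phases: int,
                   es_phase_fraction: float) -> np.ndarray:
    """Smooth cyclic per-phase volume curve (ml).

    A piecewise raised-cosine: the global maximum ``edv_ml`` sits at phase 0
    (end-diastole by generator convention), the global minimum ``esv_ml`` at
    ``round(es_phase_fraction * n_phases)``, and the curve is strictly
    monotone between the two extremes in both directions around the cycle.
    """
    if not (edv_ml >= esv_ml > 0):
        raise ValueError(f"need edv >= esv > 0, got edv={edv_ml}, esv={esv_ml}")
    if not (0 < es_phase_fraction < 1):
        raise ValueError("es_phase_fraction must lie in (0, 1)")
    if n_phases < 2:
        raise ValueError("n_phases must be at least 2")
    es = int(round(es_phase_fraction * n_phases))
    es = min(max(es, 1), n_phases - 1)
    p = np.arange(n_phases)
    curve = np.empty(n_phases, dtype=float)
    amp = edv_ml - esv_ml
    down = p <= es
    curve[down] = esv_ml + amp * (1 + np.cos(np.pi * p[down] / es)) / 2
    up = ~down
    curve[up] = esv_ml + amp * (1 - np.cos(np.pi * (p[up] - es) / (n_phases - es))) / 2
    return curve


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------
def largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return np.zeros(len(w), dtype=int)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        # ties broken by lower index for determinism
        order = np.lexsort((np.arange(len(w)), -(quota - base)))
        base[order[:short]] += 1
    return base


@dataclass
class PhantomGrid:
    """Geometry of the synthetic short-axis stack."""

    shape: tuple[int, int] = (160, 160)
    n_slices: int = 12
    in_plane_spacing_mm: tuple[float, float] = (1.25, 1.25)
    slice_thickness_mm: float = 8.0
    apical_taper: float = 0.55  # per-slice radius factor at the apex

    @property
    def voxel_volume_ml(self) -> float:
        dy, dx = self.in_plane_spacing_mm
        return dy * dx * self.slice_thickness_mm / 1000.0

    @property
    def span(self) -> tuple[int, int]:
        """Slice range occupied by the ventricles (one empty slice is kept
        below the apex and above the base for out-of-extent errors)."""
        return 1, self.n_slices - 2

    def slice_weights(self) -> np.ndarray:
        lo, hi = self.span
        n = hi - lo + 1
        taper = np.linspace(self.apical_taper, 1.0, n)
        return taper**2  # voxel share scales with radius squared


class _PhantomRasterizer:
    """Voxel-exact rasterizer for the LV-disc / RV-crescent phantom.

    Voxels are ranked once per grid by squared distance to each structure's
    in-plane centre; a slice containing N voxels of a structure is the first
    N voxels in that ranking (RV ranking skips voxels already taken by the
    LV, which clips the RV disc into a crescent hugging the LV).  Volumes
    are therefore exact to voxel rounding.
    """

    def __init__(self, grid: PhantomGrid):
        self.grid = grid
        ny, nx = grid.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        cy = ny / 2.0
        cx_lv, cx_rv = nx * 0.62, nx * 0.38
        d2_lv = (yy - cy) ** 2 + (xx - cx_lv) ** 2
        # mild anisotropy elongates the RV around the LV
        d2_rv = 0.8 * (yy - cy) ** 2 + (xx - cx_rv) ** 2
        self._order_lv = np.argsort(d2_lv, axis=None, kind="stable")
        self._order_rv = np.argsort(d2_rv, axis=None, kind="stable")
        self._d2_lv_sorted = d2_lv.ravel()[self._order_lv]
        # margin: largest disc that stays inside the grid
        self._max_r2_lv = min(cy, ny - cy, cx_lv, nx - cx_lv) ** 2
        d2_rv_sorted = d2_rv.ravel()[self._order_rv]
        self._d2_rv_sorted = d2_rv_sorted
        self._max_r2_rv = min(0.8 * cy**2, 0.8 * (ny - cy) ** 2,
                              cx_rv**2, (nx - cx_rv) ** 2)

    def rasterize_phase(self, lv_ml: float, rv_ml: float) -> np.ndarray:
        g = self.grid
        ny, nx = g.shape
        out = np.zeros((g.n_slices, ny, nx), dtype=np.uint8)
        lo, hi = g.span
        w = g.slice_weights()
        n_lv = largest_remainder(int(round(lv_ml / g.voxel_volume_ml)), w)
        n_rv = largest_remainder(int(round(rv_ml / g.voxel_volume_ml)), w)
        # keep the slice extent contiguous whenever the structure exists
        for n in (n_lv, n_rv):
            if n.sum() > 0:
                n[n == 0] = 1
        for k in range(lo, hi + 1):
            sl = out[k].ravel()
            nlv, nrv = int(n_lv[k - lo]), int(n_rv[k - lo])
            if nlv > 0:
                if self._d2_lv_sorted[nlv - 1] > self._max_r2_lv:
                    raise ValueError("LV target volume unachievable on grid")
                lv_idx = self._order_lv[:nlv]
                sl[lv_idx] = LV
            if nrv > 0:
                avail = sl[self._order_rv] == BACKGROUND
                cand = self._order_rv[avail]
                if nrv > len(cand) or self._d2_rv_sorted[avail.cumsum().searchsorted(nrv)] > self._max_r2_rv:
                    raise ValueError("RV target volume unachievable on grid")
                sl[cand[:nrv]] = RV
        return out


def rasterize_phantom(curve_lv_ml: np.ndarray, curve_rv_ml: np.ndarray,
                      grid: PhantomGrid | None = None) -> CineLabelVolume:
    """Render per-phase LV/RV volume targets into a 4D cine label volume.

    Per-phase voxel-counted volumes match the targets to voxel rounding
    (well inside the 5% fidelity contract); LV and RV never overlap; each
    structure occupies a contiguous slice range tapering toward the apex.
    """
    grid = grid or PhantomGrid()
    curve_lv_ml = np.asarray(curve_lv_ml, dtype=float)
    curve_rv_ml = np.asarray(curve_rv_ml, dtype=float)
    if curve_lv_ml.shape != curve_rv_ml.shape:
        raise ValueError("LV and RV curves must have the same number of phases")
    if (curve_lv_ml < 0).any() or (curve_rv_ml < 0).any():
        raise ValueError("volume targets must be non-negative")
    rast = _PhantomRasterizer(grid)
    phases = [rast.rasterize_phase(lv, rv)
              for lv, rv in zip(curve_lv_ml, curve_rv_ml)]
    return CineLabelVolume(np.stack(phases), grid.in_plane_spacing_mm,
                           grid.slice_thickness_mm)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------
def _draw_subject(idx: int, group: str, cfg: CohortConfig,
                  rng: np.random.Generator) -> tuple[Subject, GeneratorTruth, PhantomGrid]:
    gp = cfg.group_params[group]
    sex = "female" if rng.random() < cfg.female_fraction else "male"
    age = float(np.clip(rng.normal(*cfg.age_mean_sd), 16.0, 85.0))
    bsa = float(np.clip(rng.normal(*cfg.bsa_mean_sd), 1.3, 2.6))
    rwma = bool(rng.random() < gp.rwma_probability)
    vals, probs = gp.noncmr_points
    noncmr = int(rng.choice(vals, p=probs))
    subject = Subject(f"S{idx:04d}", sex, age, group, bsa, rwma, noncmr)

    rvedvi = float(np.clip(rng.normal(*gp.rvedvi), 40.0, 180.0))
    rvef = float(np.clip(rng.normal(*gp.rvef), 15.0, 75.0))
    lvedvi = float(np.clip(rng.normal(*gp.lvedvi), 40.0, 160.0))
    lvef = float(np.clip(rng.normal(*gp.lvef), 15.0, 80.0))
    rv_edv = rvedvi * bsa
    rv_esv = rv_edv * (1 - rvef / 100.0)
    lv_edv = lvedvi * bsa
    lv_esv = lv_edv * (1 - lvef / 100.0)

    n_phases = int(rng.integers(cfg.n_phases_range[0], cfg.n_phases_range[1] + 1))
    es_frac = float(np.clip(rng.normal(*cfg.es_fraction_mean_sd), 0.25, 0.55))
    es_phase = min(max(int(round(es_frac * n_phases)), 1), n_phases - 1)
    lv_curve = volume_profile(lv_edv, lv_esv, n_phases, es_frac)
    rv_curve = volume_profile(rv_edv, rv_esv, n_phases, es_frac)
    truth = GeneratorTruth(0, es_phase, lv_edv, lv_esv, rv_edv, rv_esv,
                           lv_curve, rv_curve)

    dxy = float(rng.uniform(*cfg.in_plane_spacing_range_mm))
    dz = float(rng.uniform(*cfg.slice_thickness_range_mm))
    grid = PhantomGrid(cfg.grid_shape, cfg.n_slices, (dxy, dxy), dz)
    return subject, truth, grid


def _group_sequence(cfg: CohortConfig, rng: np.random.Generator) -> list[str]:
    p = np.asarray(cfg.group_proportions, dtype=float)
    if cfg.exact_proportions:
        sizes = largest_remainder(cfg.n_subjects, p)
    else:
        sizes = rng.multinomial(cfg.n_subjects, p)
    seq = [g for g, n in zip(GROUPS, sizes) for _ in range(int(n))]
    rng.shuffle(seq)
    return seq


def iter_cohort(config: CohortConfig) -> Iterator[CohortRecord]:
    """Yield subjects one at a time (memory-friendly form of
    :func:`generate_cohort`); deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    groups = _group_sequence(config, rng)
    # independent per-subject streams so that subject i does not depend on
    # how many draws subject i-1 consumed
    children = np.random.SeedSequence(config.seed).spawn(len(groups))
    for i, (group, ss) in enumerate(zip(groups, children)):
        sub_rng = np.random.default_rng(ss)
        subject, truth, grid = _draw_subject(i, group, config, sub_rng)
        reference = rasterize_phantom(truth.lv_curve_ml, truth.rv_curve_ml, grid)
        reference.name = subject.id
        yield CohortRecord(subject, reference, truth)


def generate_cohort(config: CohortConfig) -> list[tuple[Subject, CineLabelVolume]]:
    """Generate the full cohort as (subject, reference segmentation) pairs."""
    return [(rec.subject, rec.reference) for rec in iter_cohort(config)]


# --------------------------------------------------------------------------
# degradation into an "automatic-like" segmentation
# --------------------------------------------------------------------------
_DILATE = ndimage.generate_binary_structure(2, 2)  # 8-connected in-plane


def _addition_pool(mask2d: np.ndarray, taken: np.ndarray) -> np.ndarray:
    """Flat indices of free voxels adjacent to (but outside) a 2D mask."""
    halo = ndimage.binary_dilation(mask2d, _DILATE, iterations=2) & ~mask2d
    return np.flatnonzero(halo.ravel() & ~taken.ravel())


def _degrade_structure(labels: np.ndarray, reference: np.ndarray, lab: int,
                       phase: int, budget: int, allocation: np.ndarray,
                       deletion_fraction: float,
                       rng: np.random.Generator) -> None:
    """Perturb `budget` voxels of one structure at one phase, in place."""
    ref3d = reference[phase] == lab
    if budget <= 0 or not ref3d.any():
        return
    slices_present = np.flatnonzero(ref3d.any(axis=(1, 2)))
    lo, hi = int(slices_present[0]), int(slices_present[-1])
    n_slices = labels.shape[1]

    counts = rng.multinomial(budget, allocation)  # basal, mid, apical, outside
    n_basal, n_mid, n_apical, n_outside = (int(c) for c in counts)
    if hi == lo:
        if n_mid or n_apical:
            warnings.warn("single-slice structure: mid/apical error budget "
                          "reallocated to the basal slice")
        n_basal += n_mid + n_apical
        n_mid = n_apical = 0

    cur = labels[phase]
    occupied = cur != BACKGROUND

    def apply_adds(k: int, pool: np.ndarray, want: int) -> int:
        take = min(want, len(pool))
        if take > 0:
            chosen = pool[rng.choice(len(pool), size=take, replace=False)]
            cur[k].ravel()[chosen] = lab
            occupied[k] = cur[k] != BACKGROUND
        return take

    overflow = 0

    def sample_into(k: int, want: int) -> int:
        """Flip up to `want` voxels in slice k, splitting the count between
        deletions and adjacent additions; return the shortfall."""
        if want <= 0:
            return 0
        dels = np.flatnonzero(ref3d[k].ravel() & (cur[k].ravel() == lab))
        adds = _addition_pool(ref3d[k], occupied[k])
        n_del = min(int(round(want * deletion_fraction)), len(dels))
        n_add = min(want - n_del, len(adds))
        n_del = min(n_del + (want - n_del - n_add), len(dels))  # backfill
        if n_del > 0:
            chosen = dels[rng.choice(len(dels), size=n_del, replace=False)]
            cur[k].ravel()[chosen] = BACKGROUND
        apply_adds(k, adds, n_add)
        return want - n_del - n_add

    overflow += sample_into(hi, n_basal)
    if hi > lo:
        overflow += sample_into(lo, n_apical)

    # outside: false positives only, in the slice just above the base or
    # just below the apex (the structure has no voxels there to delete)
    if n_outside > 0:
        pools = []
        if hi + 1 < n_slices:
            pools.append((hi + 1, _addition_pool(ref3d[hi], occupied[hi + 1])))
        if lo - 1 >= 0:
            pools.append((lo - 1, _addition_pool(ref3d[lo], occupied[lo - 1])))
        sizes = np.array([len(p[1]) for p in pools], dtype=float)
        if not pools or sizes.sum() == 0:
            warnings.warn("no slice beyond the structure's extent: outside "
                          "error budget reallocated to mid-ventricular slices")
            overflow += n_outside
        else:
            for (k, adds), want in zip(pools, largest_remainder(n_outside, sizes)):
                overflow += int(want) - apply_adds(k, adds, int(want))

    # mid-ventricular slices absorb any shortfall from the other categories
    n_mid += overflow
    if hi - lo >= 2:
        interior = np.arange(lo + 1, hi)
        weights = ref3d[interior].sum(axis=(1, 2)).astype(float)
        leftover = 0
        for k, want in zip(interior, largest_remainder(n_mid, weights)):
            leftover += sample_into(int(k), int(want))
        sample_into(int(interior[np.argmax(weights)]), leftover)
    elif n_mid > 0:
        sample_into(hi, n_mid)  # no interior slices: fall back to basal


def degrade_segmentation(reference: CineLabelVolume,
                         spec: DegradationSpec | Mapping[str, DegradationSpec],
                         phases: tuple[int, ...] | None = None,
                         seed: int | None = None) -> CineLabelVolume:
    """Corrupt a reference segmentation into an "automatic-like" one.

    By default the perturbation is applied at the ED and ES phases (the
    phases clinical measurements use), located from the reference volume
    curves; ``spec.all_phases`` extends it to the whole cycle.  ``spec`` may
    be a single :class:`DegradationSpec` or a mapping ``{"LV": ..., "RV": ...}``.
    Deterministic for a fixed seed.
    """
    specs = dict(spec) if isinstance(spec, Mapping) else {spec.structure: spec}
    out = reference.copy(name=f"{reference.name}_auto" if reference.name else "auto")
    any_all_phases = any(s.all_phases for s in specs.values())
    if phases is None:
        if any_all_phases:
            phases = tuple(range(reference.n_phases))
        else:
            totals = (reference.labels != BACKGROUND).sum(axis=(1, 2, 3))
            if totals.max() == 0:
                return out
            phases = (int(totals.argmax()), int(totals.argmin()))
            phases = tuple(dict.fromkeys(phases))  # dedupe if ED == ES

    for name, s in specs.items():
        lab = structure_label(name)
        base_seed = s.seed if s.seed is not None else seed
        rng = np.random.default_rng(base_seed)
        alloc = np.asarray(s.slice_allocation, dtype=float)
        for ph in phases:
            n_fore = int((reference.labels[ph] == lab).sum())
            budget = int(round(s.error_fraction * n_fore))
            _degrade_structure(out.labels, reference.labels, lab, ph,
                               budget, alloc, s.deletion_fraction, rng)
    return out


# --------------------------------------------------------------------------
# toy intensity rendering
# --------------------------------------------------------------------------
CLASS_INTENSITY = {"background": 40.0, "lv": 200.0, "rv": 170.0, "rim": 100.0}


def render_image(labelvol: CineLabelVolume, noise_sd: float = 10.0,
                 bias_field: bool = False, seed: int = 0,
                 class_intensity: dict[str, float] | None = None) -> np.ndarray:
    """Render a label volume into a crude cine intensity volume.

    Blood pools are bright, background dark, and a thin synthetic
    "myocardial" rim of intermediate intensity surrounds each structure;
    Gaussian noise and an optional smooth multiplicative bias field are
    added on top.  Same grid as the input; float32.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ci = dict(CLASS_INTENSITY, **(class_intensity or {}))
    lab = labelvol.labels
    img = np.full(lab.shape, ci["background"], dtype=np.float32)
    img[lab == LV] = ci["lv"]
    img[lab == RV] = ci["rv"]
    fore = lab != BACKGROUND
    for p in range(lab.shape[0]):
        for k in range(lab.shape[1]):
            rim = ndimage.binary_dilation(fore[p, k], _DILATE) & ~fore[p, k]
            img[p, k][rim] = ci["rim"]
    rng = np.random.default_rng(seed)
    if bias_field:
        coarse = rng.uniform(0.8, 1.2, size=(1, 1, 4, 4))
        ny, nx = lab.shape[2:]
        bias = ndimage.zoom(coarse, (1, 1, ny / 4, nx / 4), order=3)
        bias = np.broadcast_to(bias, lab.shape)
        img = (img * bias).astype(np.float32)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=lab.shape).astype(np.float32)
    return img.astype(np.float32)


# --------------------------------------------------------------------------
# on-disk cohort
# --------------------------------------------------------------------------
def write_cohort(records: list[CohortRecord], outdir: str | Path,
                 degraded: Mapping[str, CineLabelVolume] | None = None) -> Path:
    """Write reference (and optional degraded) volumes as 4D NIfTI plus a
    cohort CSV; returns the CSV path."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ref_path = outdir / f"{rec.subject.id}_reference.nii.gz"
        rec.reference.to_nifti(ref_path)
        row = {**asdict(rec.subject), "reference_path": ref_path.name}
        if degraded and rec.subject.id in degraded:
            auto_path = outdir / f"{rec.subject.id}_automatic.nii.gz"
            degraded[rec.subject.id].to_nifti(auto_path)
            row["automatic_path"] = auto_path.name
        rows.append(row)
    csv_path = outdir / "cohort.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
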