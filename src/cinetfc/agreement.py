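"""Agreement and evaluation statistics.

Segmentation overlap (3D Dice) and boundary distance (3D Hausdorff, in mm,
with anisotropic spacing), attribution of misclassified voxels to slice
locations (basal / mid-ventricular / apical / outside the heart), and the
method-comparison statistics: Bland–Altman bias and limits of agreement,
Pearson correlation with Fisher-z confidence interval, Cohen's kappa with
its large-sample standard error, sensitivity/specificity, and the McNemar
test for paired proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume import CineLabelVolume, structure_label

__all__ = [
    "ErrorAttribution",
    "BlandAltman",
    "dice3d",
    "hausdorff3d",
    "attribute_errors",
    "phase_difference",
    "bland_altman",
    "pearson",
    "cohens_kappa",
    "sens_spec",
    "mcnemar",
]

SLICE_CATEGORIES = ("basal", "mid_ventricular", "apical", "outside")


@dataclass
class ErrorAttribution:
    """Fractions of misclassified voxels per slice location."""

    basal: float
    mid_ventricular: float
    apical: float
    outside: float
    total_errors: int

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.basal, self.mid_ventricular, self.apical, self.outside])


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float


# --------------------------------------------------------------------------
# overlap and distance
# --------------------------------------------------------------------------
def _as_masks(a, b, structure) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, CineLabelVolume):
        a = a.labels
    if isinstance(b, CineLabelVolume):
        b = b.labels
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if structure is not None:
        lab = structure_label(structure)
        a, b = a == lab, b == lab
    return a.astype(bool), b.astype(bool)


def dice3d(a, b, structure: int | str | None = None) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of binarized structure masks.

    Two empty masks agree on absence and score 1; one empty mask scores 0.
    """
    ma, mb = _as_masks(a, b, structure)
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(mask.ndim, 1))
    return mask & ~eroded


def hausdorff3d(a, b, structure: int | str | None = None,
                spacing: tuple[float, ...] = (1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between boundary voxel centres, in mm.

    ``spacing`` gives the physical size per axis of the 3D masks (slice,
    row, col); the exact maximum is returned, not a percentile.
    """
    ma, mb = _as_masks(a, b, structure)
    if ma.ndim != 3:
        raise ValueError("hausdorff3d expects 3D masks (slice, row, col)")
    if not ma.any() or not mb.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    sp = np.asarray(spacing, dtype=float)
    pa = np.argwhere(_boundary(ma)) * sp
    pb = np.argwhere(_boundary(mb)) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0].max()
    d_ba = cKDTree(pa).query(pb, k=1)[0].max()
    return float(max(d_ab, d_ba))


def attribute_errors(auto: CineLabelVolume, reference: CineLabelVolume,
                     structure: int | str,
                     phases: tuple[int, ...]) -> ErrorAttribution:
    """Attribute misclassified voxels of one structure to slice locations.

    The symmetric difference of the automatic and reference masks is pooled
    over ``phases``; each erroneous voxel is categorized relative to the
    reference structure's slice extent at its phase — the top reference
    slice is basal, the bottom apical, interior slices mid-ventricular, and
    slices beyond the extent are outside the heart.
    """
    if not auto.same_grid(reference):
        raise ValueError("automatic and reference volumes are on different grids")
    lab = structure_label(structure)
    counts = np.zeros(4, dtype=np.int64)
    for ph in phases:
        ref = reference.labels[ph] == lab
        slices = np.flatnonzero(ref.any(axis=(1, 2)))
        if slices.size == 0:
            warnings.warn(f"reference structure empty at phase {ph}; skipped")
            continue
        lo, hi = int(slices[0]), int(slices[-1])
        diff = (auto.labels[ph] == lab) ^ ref
        per_slice = diff.sum(axis=(1, 2))
        for k, n in enumerate(per_slice):
            if n == 0:
                continue
            if k == hi:
                counts[0] += n
            elif k == lo:
                counts[2] += n
            elif lo < k < hi:
                counts[1] += n
            else:
                counts[3] += n
    total = int(counts.sum())
    frac = counts / total if total > 0 else np.zeros(4)
    return ErrorAttribution(float(frac[0]), float(frac[1]), float(frac[2]),
                            float(frac[3]), total)


# --------------------------------------------------------------------------
# method-comparison statistics
# --------------------------------------------------------------------------
def phase_difference(auto_phase: int, manual_phase: int, n_phases: int) -> float:
    """Signed circular phase difference as a percentage of the cardiac cycle.

    The raw index difference (auto − manual) is wrapped to
    (−n_phases/2, n_phases/2] before scaling, so a difference across the
    cycle boundary counts as small.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be at least 2")
    if not (0 <= auto_phase < n_phases and 0 <= manual_phase < n_phases):
        raise ValueError("phases must lie in [0, n_phases)")
    d = (auto_phase - manual_phase) % n_phases
    if d > n_phases / 2:
        d -= n_phases
    return 100.0 * d / n_phases


def bland_altman(x, y) -> BlandAltman:
    """Bland–Altman bias and 95% limits of agreement (bias ± 1.96·SD)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


def pearson(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson product-moment r with a Fisher-z confidence interval."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance series")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if n < 4 or abs(r) == 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def cohens_kappa(a, b) -> tuple[float, float]:
    """Unweighted Cohen's kappa and its large-sample standard error.

    κ = (p_o − p_e)/(1 − p_e); SE = sqrt(p_o(1 − p_o)/(n(1 − p_e)²)).  When
    both raters use a single identical category, agreement is perfect but
    chance-corrected agreement is undefined; κ is reported as 1 with a
    warning.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("a and b must be equal-length non-empty 1D series")
    cats = np.union1d(a, b)
    n = len(a)
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    table = np.zeros((len(cats), len(cats)))
    np.add.at(table, (ai, bi), 1)
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    if np.isclose(pe, 1.0):
        warnings.warn("single category on both sides: kappa undefined; "
                      "reporting 1 for perfect agreement")
        return (1.0 if po == 1.0 else 0.0), 0.0
    kappa = (po - pe) / (1 - pe)
    se = np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return float(kappa), float(se)


def sens_spec(test: np.ndarray, condition: np.ndarray) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) of a binary test
    against a binary condition; an undefined metric is returned as NaN."""
    test = np.asarray(test, bool)
    condition = np.asarray(condition, bool)
    if test.shape != condition.shape:
        raise ValueError("series must have equal length")
    tp = int((test & condition).sum())
    fn = int((~test & condition).sum())
    tn = int((~test & ~condition).sum())
    fp = int((test & ~condition).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def mcnemar(paired_a, paired_b) -> float:
    """McNemar test p-value for two paired binary classifications.

    Exact binomial when fewer than 25 discordant pairs, chi-square with
    continuity correction otherwise; no discordant pairs gives p = 1.
    """
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    a = np.asarray(paired_a, bool)
    b = np.asarray(paired_b, bool)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    if n01 + n10 == 0:
        return 1.0
    table = [[int((a & b).sum()), n10], [n01, int((~a & ~b).sum())]]
    exact = (n01 + n10) < 25
    res = sm_mcnemar(table, exact=exact, correction=True)
    return float(res.pvalue)
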