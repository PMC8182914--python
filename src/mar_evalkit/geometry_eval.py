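"""Geometric fidelity metrics and statistics.

Implements the quantitative evaluation of corrected CT volumes against the
artifact-free Reference: planning-margin expansion (CTV -> PTV), RMSE and
SSIM restricted to a region of interest, the overlap ratio of the corrected
region with the PTV, ordinary-least-squares regression of SSIM on overlap
ratio, one-way ANOVA across correction conditions, and the Mann-Whitney U
test.  The significance convention throughout is alpha = 0.05.

SSIM uses the canonical constants (Gaussian window sigma 1.5 truncated at
11x11, k1 = 0.01, k2 = 0.03) with a fixed data range of 2000 HU so that no
per-volume rescaling contaminates cross-condition comparisons; local SSIM
maps are computed slice-wise in 2D (the artifact mechanism is slice-wise)
and averaged over the ROI voxels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .errors import MetricError, ValidationError
from .volume_io import CTVolume, VoxelMask

SSIM_DATA_RANGE_HU = 2000.0
ALPHA = 0.05


@dataclasses.dataclass
class MetricRecord:
    """One evaluation row: a (case, scheme, condition) triple."""

    case_id: str
    scheme: str  # m4 | m8
    condition: str  # artifacts | water | mar
    rmse_hu: float
    ssim: float
    overlap_ratio: float
    ptv_ml: float

    def __post_init__(self):
        if self.scheme not in ("m4", "m8"):
            raise ValidationError(f"scheme must be m4 or m8, got {self.scheme!r}")
        if self.condition not in ("artifacts", "water", "mar"):
            raise ValidationError(f"condition must be artifacts/water/mar, got {self.condition!r}")
        if not (0.0 <= self.ssim <= 1.0):
            raise ValidationError(f"ssim must be in [0, 1], got {self.ssim}")
        if self.rmse_hu < 0:
            raise ValidationError("rmse_hu must be >= 0")
        if not (0.0 <= self.overlap_ratio <= 1.0):
            raise ValidationError(f"overlap_ratio must be in [0, 1], got {self.overlap_ratio}")


@dataclasses.dataclass
class RegressionFit:
    """OLS fit of SSIM on overlap ratio (one line of the scatter analysis)."""

    slope: float
    intercept: float
    n_points: int


def expand_margin(ctv: VoxelMask, margin_mm: float = 5.0) -> VoxelMask:
    """Expand a CTV mask by a physical margin (Euclidean, mm) into the PTV.

    A voxel belongs to the PTV iff its center lies within ``margin_mm`` of
    some CTV voxel center; anisotropic spacing is honored.  CTV is always a
    subset of the result.
    """
    if margin_mm < 0:
        raise ValidationError("margin_mm must be >= 0")
    if margin_mm == 0 or not ctv.data.any():
        return ctv.copy(label="ptv")
    dist = ndimage.distance_transform_edt(~ctv.data, sampling=ctv.spacing)
    return ctv.copy(data=dist <= margin_mm, label="ptv")


def _check_roi(ref: CTVolume, test: CTVolume, roi: VoxelMask) -> None:
    ref.require_aligned(test, "test volume")
    ref.require_aligned(roi, "roi mask")
    if not roi.data.any():
        raise MetricError("metric undefined for an empty ROI")


def rmse_in_roi(ref: CTVolume, test: CTVolume, roi: VoxelMask) -> float:
    """Root-mean-square HU error over the ROI voxels."""
    _check_roi(ref, test, roi)
    diff = test.data[roi.data] - ref.data[roi.data]
    return float(np.sqrt(np.mean(diff**2)))


def ssim_in_roi(
    ref: CTVolume,
    test: CTVolume,
    roi: VoxelMask,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = SSIM_DATA_RANGE_HU,
    sigma: float = 1.5,
) -> float:
    """Mean of the local SSIM map over ROI voxels, clamped to [0, 1].

    The local map is computed per axial slice with a Gaussian-weighted
    window (C1 = (k1*data_range)^2, C2 = (k2*data_range)^2).
    """
    from skimage.metrics import structural_similarity

    _check_roi(ref, test, roi)
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be an odd integer >= 3")
    if window > min(ref.shape[1], ref.shape[2]):
        raise ValidationError("window does not fit within the slice extent")
    total = 0.0
    count = 0
    for z in range(ref.shape[0]):
        m = roi.data[z]
        if not m.any():
            continue
        _, smap = structural_similarity(
            ref.data[z],
            test.data[z],
            win_size=window,
            data_range=data_range,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            K1=k1,
            K2=k2,
            full=True,
        )
        total += float(smap[m].sum())
        count += int(m.sum())
    return float(np.clip(total / count, 0.0, 1.0))


def overlap_ratio(corrected_region: VoxelMask, ptv: VoxelMask) -> float:
    """|corrected_region ∩ PTV| / |PTV|."""
    corrected_region.require_aligned(ptv, "ptv mask")
    n_ptv = ptv.voxel_count()
    if n_ptv == 0:
        raise MetricError("overlap ratio undefined for an empty PTV")
    return float((corrected_region.data & ptv.data).sum() / n_ptv)


def fit_linear(points: Sequence[Tuple[float, float]]) -> RegressionFit:
    """Ordinary least squares fit of y on x for (x, y) pairs."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValidationError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValidationError("degenerate fit: all x values are equal")
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept), n_points=len(x))


def anova_oneway(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """One-way ANOVA F statistic and p value across >= 2 groups.

    Groups with zero between-group variance return (F=0, p=1) even when the
    within-group variance is also zero.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValidationError("every group needs at least two values")
    means = [g.mean() for g in arrays]
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (m - grand) ** 2 for g, m in zip(arrays, means))
    if ss_between == 0:
        return 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when n_a + n_b <= 12 and the samples are free of
    ties; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def evaluate_condition(
    ref: CTVolume,
    test: CTVolume,
    ptv: VoxelMask,
    corrected_region: VoxelMask,
    case_id: str,
    scheme: str,
    condition: str,
    ssim_kwargs: dict | None = None,
) -> MetricRecord:
    """Build one MetricRecord for a (case, scheme, condition) triple."""
    return MetricRecord(
        case_id=case_id,
        scheme=scheme,
        condition=condition,
        rmse_hu=rmse_in_roi(ref, test, ptv),
        ssim=ssim_in_roi(ref, test, ptv, **(ssim_kwargs or {})),
        overlap_ratio=overlap_ratio(corrected_region, ptv),
        ptv_ml=ptv.physical_volume_ml,
    )
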