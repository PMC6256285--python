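"""Object-based colocalization, spine/shaft enrichment and intensity regression.

Colocalization here is object-based: the fraction of one channel's puncta
that share voxels with any punctum of the other channel
(n overlapping A / n A). Both directions are computed with their own
denominators, since the measure is asymmetric. Pixel-correlation
coefficients (Pearson/Manders) are deliberately not provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .puncta import LabelMap


@dataclass
class ColocResult:
    """Pairwise object-overlap summary between two labeled channels."""

    n_a: int
    n_b: int
    n_overlap_a: int                 # A puncta sharing >= min voxels with any B punctum
    n_overlap_b: int
    fraction_a_with_b: float | None  # None (undefined), never 0, when n_a == 0
    fraction_b_with_a: float | None
    overlapping_ids_a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    overlapping_ids_b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    min_shared_voxels: int = 1
    overlap_density_per_100um: float | None = None
    overlap_mean_intensity_a: float | None = None
    overlap_mean_intensity_b: float | None = None
    overlap_volumes_um3: np.ndarray | None = None


@dataclass
class EnrichmentRatio:
    """Spine vs dendritic-shaft intensity enrichment.

    ratio = spine/shaft: 0 means the protein sits exclusively in shaft
    (immature) puncta; 1 means equal contribution to shaft puncta and spines.
    """

    spine_intensity: float
    shaft_intensity: float
    ratio: float | None


@dataclass
class RegressionSlope:
    slope: float
    intercept: float
    r2: float
    n_points: int


def _pair_counts(labels_a: np.ndarray, labels_b: np.ndarray) -> dict[tuple[int, int], int]:
    """Shared-voxel counts for every (A label, B label) pair that intersects."""
    both = (labels_a > 0) & (labels_b > 0)
    if not np.any(both):
        return {}
    a = labels_a[both].astype(np.int64)
    b = labels_b[both].astype(np.int64)
    key = a * (labels_b.max() + 1) + b
    uniq, counts = np.unique(key, return_counts=True)
    kb = labels_b.max() + 1
    return {(int(k // kb), int(k % kb)): int(c) for k, c in zip(uniq, counts)}


def overlap_fraction(
    labels_a: LabelMap, labels_b: LabelMap, min_shared_voxels: int = 1
) -> ColocResult:
    """Fraction of A puncta overlapping any B punctum (and vice versa).

    An A punctum counts as overlapping if it shares at least
    ``min_shared_voxels`` voxels with some single B punctum; each punctum is
    counted at most once. With zero A puncta the fraction is undefined and
    reported as None, never as 0.
    """
    if labels_a.labels.shape != labels_b.labels.shape:
        raise ValueError("label maps must share a grid")
    pairs = _pair_counts(labels_a.labels, labels_b.labels)
    ids_a = sorted({a for (a, b), c in pairs.items() if c >= min_shared_voxels})
    ids_b = sorted({b for (a, b), c in pairs.items() if c >= min_shared_voxels})
    n_a, n_b = labels_a.n_puncta, labels_b.n_puncta
    return ColocResult(
        n_a=n_a,
        n_b=n_b,
        n_overlap_a=len(ids_a),
        n_overlap_b=len(ids_b),
        fraction_a_with_b=(len(ids_a) / n_a) if n_a else None,
        fraction_b_with_a=(len(ids_b) / n_b) if n_b else None,
        overlapping_ids_a=np.asarray(ids_a, dtype=int),
        overlapping_ids_b=np.asarray(ids_b, dtype=int),
        min_shared_voxels=min_shared_voxels,
    )


def overlap_metrics(
    labels_a: LabelMap,
    labels_b: LabelMap,
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    voxel_size,
    dendrite_length_um: float,
    min_shared_voxels: int = 1,
) -> ColocResult:
    """Overlap fractions plus density (per 100 um), intensity and volume stats.

    Intensity and volume statistics are computed over the A puncta that
    overlap B (mean of per-punctum mean intensities; per-punctum volumes).
    """
    if dendrite_length_um is None or dendrite_length_um <= 0:
        raise ValueError("dendrite length must be positive")
    res = overlap_fraction(labels_a, labels_b, min_shared_voxels)
    res.overlap_density_per_100um = res.n_overlap_a / dendrite_length_um * 100.0
    if res.n_overlap_a:
        from scipy import ndimage

        la = labels_a.labels
        ids = res.overlapping_ids_a
        cnts = ndimage.sum_labels(np.ones_like(la, dtype=float), la, ids)
        res.overlap_mean_intensity_a = float(
            np.mean(ndimage.sum_labels(np.asarray(raw_a, float), la, ids) / cnts)
        )
        unit = float(np.prod(np.asarray(voxel_size, dtype=float)[-la.ndim:]))
        res.overlap_volumes_um3 = np.asarray(cnts) * unit
    if res.n_overlap_b:
        from scipy import ndimage

        lb = labels_b.labels
        idsb = res.overlapping_ids_b
        cntsb = ndimage.sum_labels(np.ones_like(lb, dtype=float), lb, idsb)
        res.overlap_mean_intensity_b = float(
            np.mean(ndimage.sum_labels(np.asarray(raw_b, float), lb, idsb) / cntsb)
        )
    return res


def triple_overlap(
    labels_a: LabelMap, labels_b: LabelMap, labels_c: LabelMap, min_shared_voxels: int = 1
) -> float | None:
    """Fraction of A puncta overlapping both a B and a C punctum (A∩B∩C)."""
    ab = overlap_fraction(labels_a, labels_b, min_shared_voxels)
    ac = overlap_fraction(labels_a, labels_c, min_shared_voxels)
    if ab.n_a == 0:
        return None
    common = np.intersect1d(ab.overlapping_ids_a, ac.overlapping_ids_a)
    return common.size / ab.n_a


def non_overlapping_ids(labels_a: LabelMap, result: ColocResult) -> np.ndarray:
    """Complement set: A puncta with no qualifying overlap.

    Guaranteed to partition A exactly together with ``overlapping_ids_a``.
    """
    all_ids = np.arange(1, labels_a.n_puncta + 1)
    return np.setdiff1d(all_ids, result.overlapping_ids_a)


def spine_shaft_ratio(
    image: np.ndarray,
    spine_rois: list[tuple[int, int, int, int]],
    shaft_rois: list[tuple[int, int, int, int]],
    background: float = 0.0,
) -> EnrichmentRatio:
    """Spine/shaft enrichment from a sum projection and two ROI sets.

    Each term is the integrated (summed) background-subtracted intensity over
    its ROI boxes (y0, y1, x0, x1, half-open). Zero shaft intensity leaves
    the ratio undefined (None); zero spine intensity gives ratio 0.
    """
    img = np.asarray(image, dtype=float)
    if not spine_rois or not shaft_rois:
        raise ValueError("both ROI sets must be non-empty")

    cover = np.zeros(img.shape, dtype=np.int8)
    for (y0, y1, x0, x1) in [*spine_rois, *shaft_rois]:
        if y1 <= y0 or x1 <= x0:
            raise ValueError("empty ROI box")
        cover[y0:y1, x0:x1] += 1
    if cover.max() > 1:
        raise ValueError("ROIs must be disjoint")

    def total(rois) -> float:
        return float(
            sum(np.clip(img[y0:y1, x0:x1] - background, 0, None).sum() for y0, y1, x0, x1 in rois)
        )

    spine, shaft = total(spine_rois), total(shaft_rois)
    ratio = (spine / shaft) if shaft > 0 else None
    return EnrichmentRatio(spine_intensity=spine, shaft_intensity=shaft, ratio=ratio)


def puncta_regression(x_intensities, y_intensities) -> RegressionSlope:
    """OLS regression of per-punctum channel-Y vs channel-X intensities."""
    x = np.asarray(x_intensities, dtype=float)
    y = np.asarray(y_intensities, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need >= 3 points for a regression slope")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionSlope(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_points=int(x.size),
    )
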