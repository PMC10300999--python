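"""Breast segmentation, pectoral removal, ROI delineation, normalization.

The breast is segmented by Otsu thresholding followed by largest-component
selection, morphological opening and hole filling.  On MLO views the
pectoral muscle appears as a bright wedge in the chest-wall corner; its
boundary is found by a straight-line Hough transform on the Canny edge map
restricted to that corner, and mask pixels on the chest-wall side of the
accepted line are removed.  Three regions of interest are then delineated:

* ``square``       — the largest axis-aligned square fully inside the mask;
* ``retroareolar`` — a square of side 0.25 x breast depth centred on the
  nipple point (the contour point farthest from the chest wall);
* ``whole``        — the mask bounding-box crop.

All views are canonicalized so the chest wall is on the left (right-side
views are mirrored); coordinates are 0-based (row, col) with half-open
bounding boxes.  Out-of-mask pixels are carried as an explicit validity
mask and excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, morphology, transform

from .errors import InputError, NormalizationError, RoiError, SegmentationError

__all__ = [
    "BreastMask",
    "RoiImage",
    "mirror_to_chest_left",
    "segment_breast",
    "remove_pectoral",
    "extract_rois",
    "zscore_roi",
]

VIEW_TAGS = ("LCC", "RCC", "LMLO", "RMLO")


@dataclass
class BreastMask:
    """Binary breast mask plus derived landmarks (chest wall at column 0)."""

    mask: np.ndarray
    pectoral_line: tuple[tuple[float, float], tuple[float, float]] | None = None
    nipple_point: tuple[int, int] = (0, 0)


@dataclass
class RoiImage:
    """A pixel patch with validity mask; invalid pixels carry no statistics."""

    pixels: np.ndarray
    valid: np.ndarray
    roi_kind: str  # square | retroareolar | whole
    view_tag: str
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    normalized: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.pixels.shape != self.valid.shape:
            raise InputError("pixels and valid mask shapes differ")
        if self.roi_kind == "square" and self.pixels.shape[0] != self.pixels.shape[1]:
            raise InputError("square ROI must be square")

    @property
    def values(self) -> np.ndarray:
        return self.pixels[self.valid]


def mirror_to_chest_left(view: np.ndarray, view_tag: str) -> np.ndarray:
    """Flip right-side views so the chest wall lies along column 0."""
    if view_tag not in VIEW_TAGS:
        raise InputError(f"unknown view tag {view_tag!r}")
    return np.fliplr(view) if view_tag.startswith("R") else np.asarray(view)


def _nipple_point(mask: np.ndarray) -> tuple[int, int]:
    """Contour point of maximal chest-wall distance (largest column)."""
    rows, cols = np.nonzero(mask)
    cmax = cols.max()
    cand = np.sort(rows[cols == cmax])
    return int(cand[len(cand) // 2]), int(cmax)


def segment_breast(view: np.ndarray, opening_radius: int = 5, smooth_sigma: float = 3.0) -> BreastMask:
    """Otsu threshold -> largest component -> opening -> hole fill.

    The image is Gaussian-smoothed (``smooth_sigma``) before thresholding so
    Otsu separates breast from background rather than splitting the breast's
    own texture; the mask itself is built at full resolution.
    """
    view = np.asarray(view, dtype=float)
    if view.ndim != 2:
        raise InputError("view must be a 2-D single-channel image")
    if not np.isfinite(view).all() or view.min() == view.max():
        raise SegmentationError("blank or constant image cannot be segmented")
    smoothed = ndimage.gaussian_filter(view, smooth_sigma) if smooth_sigma > 0 else view
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        raise SegmentationError("no foreground after thresholding")
    labels = measure.label(fg, connectivity=1)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius))
    if not mask.any():
        raise SegmentationError("mask vanished under morphological opening")
    labels = measure.label(mask, connectivity=1)  # opening can split
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return BreastMask(mask=mask, nipple_point=_nipple_point(mask))


def _line_endpoints(angle: float, dist: float, shape) -> tuple[tuple[float, float], tuple[float, float]]:
    """Intersections of a Hough (angle, dist) line with the image border.

    skimage parameterizes lines as ``dist = col*cos(angle) + row*sin(angle)``.
    """
    h, w = shape
    pts = []
    ca, sa = np.cos(angle), np.sin(angle)
    if abs(sa) > 1e-9:
        for c in (0.0, w - 1.0):
            r = (dist - c * ca) / sa
            if -1e-6 <= r <= h - 1 + 1e-6:
                pts.append((float(np.clip(r, 0, h - 1)), c))
    if abs(ca) > 1e-9:
        for r in (0.0, h - 1.0):
            c = (dist - r * sa) / ca
            if -1e-6 <= c <= w - 1 + 1e-6:
                pts.append((r, float(np.clip(c, 0, w - 1))))
    uniq = []
    for p in pts:
        if all(abs(p[0] - q[0]) + abs(p[1] - q[1]) > 1e-6 for q in uniq):
            uniq.append(p)
    if len(uniq) < 2:
        return None
    return uniq[0], uniq[1]


def remove_pectoral(
    view: np.ndarray,
    mask: BreastMask,
    view_tag: str,
    canny_sigma: float = 2.0,
    min_angle_deg: float = 10.0,
    max_angle_deg: float = 80.0,
    vote_fraction: float = 0.35,
) -> BreastMask:
    """Drop the pectoral wedge from an MLO mask via Hough line detection.

    The Canny edge map is restricted to the chest-wall upper quadrant of the
    mask bounding box; the highest-vote straight line inclined 10-80 degrees
    from vertical is accepted if its votes exceed ``vote_fraction`` of the
    quadrant diagonal.  Pixels on the chest-wall (upper-left) side of the
    line are removed.  With no acceptable line the mask is returned
    unchanged and ``pectoral_line`` stays absent.
    """
    if "MLO" not in view_tag:
        raise InputError("remove_pectoral applies to MLO views only")
    view = np.asarray(view, dtype=float)
    m = mask.mask
    rows, cols = np.nonzero(m)
    r1, c1 = rows.max() + 1, cols.max() + 1
    qr, qc = r1 // 2, c1 // 2
    edges = feature.canny(view, sigma=canny_sigma)
    quad = np.zeros_like(edges)
    quad[:qr, :qc] = edges[:qr, :qc] & m[:qr, :qc]
    if not quad.any():
        return mask

    # hough angle is the line-normal angle; a vertical line has angle 0, so
    # inclination from vertical = |angle| — search both signs
    span = np.linspace(min_angle_deg, max_angle_deg, 141)
    thetas = np.deg2rad(np.concatenate([-span[::-1], span]))
    hspace, angles, dists = transform.hough_line(quad, theta=thetas)
    threshold = vote_fraction * np.hypot(qr, qc) * 0.5
    peaks = transform.hough_line_peaks(hspace, angles, dists, num_peaks=5)
    best = None
    for votes, angle, dist in zip(*peaks):
        if votes < threshold:
            continue
        if best is None or votes > best[0]:
            best = (votes, angle, dist)
    if best is None:
        return mask
    _, angle, dist = best
    ends = _line_endpoints(angle, dist, view.shape)
    if ends is None:
        return mask

    rr, cc = np.mgrid[0 : view.shape[0], 0 : view.shape[1]]
    side = cc * np.cos(angle) + rr * np.sin(angle) - dist
    corner_side = 0 * np.cos(angle) + 0 * np.sin(angle) - dist  # chest-wall corner (0,0)
    new = m & ~(np.sign(side) == np.sign(corner_side))
    if not new.any():
        return mask
    labels = measure.label(new, connectivity=1)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    new = labels == largest
    return BreastMask(mask=new, pectoral_line=ends, nipple_point=_nipple_point(new))


def _square_fit_positions(sat: np.ndarray, s: int) -> np.ndarray:
    """Boolean map over top-left corners where an s x s all-true window fits."""
    sums = sat[s:, s:] - sat[:-s, s:] - sat[s:, :-s] + sat[:-s, :-s]
    return sums == s * s


def _largest_inscribed_square(mask: np.ndarray) -> tuple[int, int, int]:
    """(side, top_row, left_col) of the largest square inside ``mask``.

    Binary search on the side length using an integral image; ties resolved
    to the smallest top-left row, then column.
    """
    m = mask.astype(np.int64)
    if not m.any():
        return (0, 0, 0)
    sat = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(m, axis=0), axis=1, out=sat[1:, 1:])
    lo, hi = 1, min(m.shape)  # lo always feasible once mask non-empty
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _square_fit_positions(sat, mid).any():
            lo = mid
        else:
            hi = mid - 1
    fits = _square_fit_positions(sat, lo)
    rows, cols = np.nonzero(fits)
    k = np.lexsort((cols, rows))[0]
    return lo, int(rows[k]), int(cols[k])


def extract_rois(
    view: np.ndarray,
    mask: BreastMask,
    view_tag: str = "LCC",
    ra_fraction: float = 0.25,
    min_square: int = 8,
) -> dict[str, RoiImage]:
    """Delineate the square, retroareolar and whole-breast ROIs."""
    view = np.asarray(view, dtype=float)
    m = mask.mask
    if not m.any():
        raise RoiError("empty mask")

    side, r0, c0 = _largest_inscribed_square(m)
    if side < min_square:
        raise RoiError(f"mask admits no inscribed square of side >= {min_square}")
    sq = RoiImage(
        pixels=view[r0 : r0 + side, c0 : c0 + side],
        valid=np.ones((side, side), dtype=bool),
        roi_kind="square",
        view_tag=view_tag,
        bbox=(r0, c0, r0 + side, c0 + side),
    )

    rows, cols = np.nonzero(m)
    depth = int(cols.max() - cols.min() + 1)
    ra_side = max(min_square, int(round(ra_fraction * depth)))
    nr, nc = mask.nipple_point
    rr0 = int(np.clip(nr - ra_side // 2, 0, view.shape[0] - 1))
    cc0 = int(np.clip(nc - ra_side // 2, 0, view.shape[1] - 1))
    rr1 = min(view.shape[0], rr0 + ra_side)
    cc1 = min(view.shape[1], cc0 + ra_side)
    ra_valid = m[rr0:rr1, cc0:cc1]
    if not ra_valid.any():
        raise RoiError("retroareolar ROI contains no in-mask pixels")
    ra = RoiImage(
        pixels=view[rr0:rr1, cc0:cc1],
        valid=ra_valid,
        roi_kind="retroareolar",
        view_tag=view_tag,
        bbox=(rr0, cc0, rr1, cc1),
    )

    br0, br1 = int(rows.min()), int(rows.max() + 1)
    bc0, bc1 = int(cols.min()), int(cols.max() + 1)
    whole = RoiImage(
        pixels=view[br0:br1, bc0:bc1],
        valid=m[br0:br1, bc0:bc1],
        roi_kind="whole",
        view_tag=view_tag,
        bbox=(br0, bc0, br1, bc1),
    )
    return {"square": sq, "retroareolar": ra, "whole": whole}


def zscore_roi(roi: RoiImage) -> RoiImage:
    """Z-score over in-mask pixels (population SD); original left untouched."""
    vals = roi.values
    if vals.size < 2:
        raise NormalizationError("need at least 2 in-mask pixels")
    mu = vals.mean()
    sd = vals.std(ddof=0)
    if sd == 0:
        raise NormalizationError("zero variance: cannot z-score a constant ROI")
    pix = (roi.pixels - mu) / sd
    return replace(roi, pixels=pix, normalized=True)
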