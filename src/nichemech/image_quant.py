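"""Particle counting, masked intensity, and adhesion-assay quantifications.

Generic image operators following the "analyze particles" / masked-intensity
conventions common in fluorescence quantification, plus three assay
read-outs:

* enzyme detachment — whole-well cell counts before/after dissociation, with
  the well border excluded by a fixed pixel margin; reported as
  ``100 * after / before`` percent remaining;
* centrifugation detachment — fractional area covered by cells inside a
  centered circular crop, before/after spinning;
* Matrigel dispersion — maximum Euclidean reach of cells beyond the initial
  spotting perimeter.

Thresholds are always explicit parameters.  An Otsu helper exists for
exploration but is never applied silently, matching the practice of fixing
one threshold per experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

__all__ = [
    "LabeledParticles",
    "count_particles",
    "percent_remaining",
    "restrict_margin",
    "crop_circle",
    "area_fraction",
    "percent_area_remaining",
    "masked_intensity",
    "dispersion_distance",
    "otsu_threshold",
]


@dataclass
class LabeledParticles:
    """Disjoint labeled particles with areas and centroids.

    ``areas`` are in um^2 when a pixel size is supplied, else px^2.
    """

    labels: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray  # (n, 2) row/col
    pixel_size: float = 1.0

    @property
    def count(self) -> int:
        return int(self.areas.size)


def otsu_threshold(image) -> float:
    """Otsu's automatic threshold — offered for exploration, never a default."""
    return float(threshold_otsu(np.asarray(image)))


def count_particles(
    image,
    threshold,
    min_area=0.0,
    watershed_split=False,
    roi_mask=None,
    pixel_size=1.0,
) -> LabeledParticles:
    """Threshold, optionally watershed-split, and count particles.

    Pixels ``>= threshold`` (within ``roi_mask`` if given) are foreground.
    With ``watershed_split``, touching particles are divided along the ridge
    lines of the Euclidean distance transform, seeded at its local maxima.
    Particles smaller than ``min_area`` (same units as ``areas``) are
    dropped.
    """
    image = np.asarray(image, dtype=float)
    binary = image >= threshold
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != image.shape:
            raise ValueError("roi_mask shape must match image")
        if not roi_mask.any():
            warnings.warn("empty ROI; particle count is 0", stacklevel=2)
        binary &= roi_mask

    if watershed_split and binary.any():
        distance = ndi.distance_transform_edt(binary)
        seeds = peak_local_max(
            distance,
            labels=cc_label(binary, connectivity=2),
            min_distance=1,
            exclude_border=False,
        )
        peak_mask = np.zeros(binary.shape, dtype=bool)
        peak_mask[tuple(seeds.T)] = True
        # plateau maxima (e.g. the center of a symmetric disk) come back as
        # several adjacent points; connected peaks must seed one basin
        markers = cc_label(peak_mask, connectivity=2)
        labels = watershed(-distance, markers, mask=binary, connectivity=2)
    else:
        labels = cc_label(binary, connectivity=2)

    px_area = pixel_size**2
    out = np.zeros_like(labels, dtype=np.int32)
    areas, cents = [], []
    nxt = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = mask.sum() * px_area
        if area <= 0 or area < min_area:
            continue
        nxt += 1
        out[mask] = nxt
        areas.append(area)
        rr, cc = np.nonzero(mask)
        cents.append((rr.mean(), cc.mean()))
    return LabeledParticles(
        out,
        np.asarray(areas, dtype=float),
        np.asarray(cents, dtype=float).reshape(-1, 2),
        pixel_size,
    )


def percent_remaining(count_before, count_after) -> float:
    """Percent of cells remaining after detachment: 100 * after / before."""
    if count_before <= 0:
        raise ValueError("count_before must be > 0")
    return 100.0 * count_after / count_before


def restrict_margin(shape, margin_px) -> np.ndarray:
    """Boolean ROI excluding a border band of ``margin_px`` on every side.

    ``shape`` may be an image array or a (rows, cols) tuple.  Mirrors the
    well-edge restriction used to exclude debris accumulating at well edges.
    """
    if hasattr(shape, "shape"):
        shape = shape.shape
    rows, cols = shape
    if margin_px < 0:
        raise ValueError("margin must be >= 0")
    if margin_px >= min(rows, cols) / 2:
        raise ValueError("margin leaves no interior pixels")
    mask = np.zeros((rows, cols), dtype=bool)
    if margin_px == 0:
        mask[:] = True
    else:
        mask[margin_px:-margin_px, margin_px:-margin_px] = True
    return mask


def crop_circle(shape, radius_px, center=None) -> np.ndarray:
    """Boolean ROI of a centered disk of ``radius_px`` (pixel centers).

    Mirrors the circular crop applied to whole-well images before computing
    covered area.
    """
    if hasattr(shape, "shape"):
        shape = shape.shape
    rows, cols = shape
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if radius_px > min(rows, cols) / 2.0:
        raise ValueError("circle does not fit inside the image")
    rr, cc = np.ogrid[:rows, :cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def area_fraction(image, threshold, roi_mask=None) -> float:
    """Percent of the ROI covered by pixels >= threshold (0-100)."""
    image = np.asarray(image, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(image.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    covered = (image >= threshold) & roi_mask
    return 100.0 * covered.sum() / roi_mask.sum()


def percent_area_remaining(before_pct, after_pct) -> float:
    """Percent of covered area remaining after spinning: 100 * after / before.

    The after/before orientation matches the enzyme assay so both detachment
    read-outs increase with adhesion strength.
    """
    if before_pct <= 0:
        raise ValueError("coverage before spinning must be > 0")
    return 100.0 * after_pct / before_pct


def masked_intensity(image, cell_mask):
    """Total intensity within each cell mask, normalized by cell size.

    Returns a dict ``cell_id -> dict`` with the summed pixel intensity
    (RawIntDen), area in px, and the size-normalized intensity (sum / area).
    ``cell_mask`` is a labeled integer image (0 = background).
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask)
    if cell_mask.shape != image.shape:
        raise ValueError("cell mask shape must match image")
    out = {}
    for cid in np.unique(cell_mask):
        if cid <= 0:
            continue
        mask = cell_mask == cid
        area = int(mask.sum())
        if area == 0:
            raise ValueError(f"cell {cid} has zero area")
        total = float(image[mask].sum())
        out[int(cid)] = {
            "raw_integrated_density": total,
            "area_px": area,
            "normalized_intensity": total / area,
        }
    return out


def _boundary_4adjacent(mask) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (or on the image edge)."""
    eroded = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def dispersion_distance(mask_t0, mask_t, pixel_size=1.0) -> float:
    """Maximum reach of cells beyond the initial spotting perimeter (um).

    The perimeter is the 4-adjacent boundary of ``mask_t0``; the distance is
    the largest pixel-center Euclidean distance from any ``mask_t``
    foreground pixel *outside* ``mask_t0`` to that boundary.  Returns 0 when
    ``mask_t`` is contained in ``mask_t0``.
    """
    mask_t0 = np.asarray(mask_t0, dtype=bool)
    mask_t = np.asarray(mask_t, dtype=bool)
    if mask_t0.shape != mask_t.shape:
        raise ValueError("masks must share a shape")
    if not mask_t0.any():
        raise ValueError("initial mask is empty")
    if not mask_t.any():
        raise ValueError("timepoint mask is empty")
    outside = mask_t & ~mask_t0
    if not outside.any():
        return 0.0
    boundary = _boundary_4adjacent(mask_t0)
    tree = cKDTree(np.argwhere(boundary))
    dists, _ = tree.query(np.argwhere(outside))
    return float(dists.max() * pixel_size)
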