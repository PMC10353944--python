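"""FRET tension-sensor force mapping and adhesion segmentation.

Cells plated on a surface coated with RGD molecular tension sensors pull on
integrin-bound sensor molecules; stretching the sensor separates its
donor/acceptor pair, so higher force means lower FRET efficiency.  This
module turns a donor/acceptor TIRF image pair into a per-pixel efficiency
map, inverts a monotone calibration curve to obtain a force map (pN),
segments force-producing adhesions by thresholding plus watershed splitting,
and summarizes forces per cell and per animal group.

The per-pixel efficiency uses the sensitized-emission proximity ratio

    E = A' / (A' + gamma * D'),   D' = donor - bg_d,   A' = acceptor - bg_a - beta * D'

with configurable donor bleed-through ``beta`` and detection ratio ``gamma``
(defaults 0 and 1).  Pixels whose background-corrected total intensity falls
below a floor are marked invalid rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .stats import (
    GroupComparison,
    fisher_exact_two_sided,
    mann_whitney_two_tailed,
)

__all__ = [
    "CalibrationCurve",
    "EfficiencyMap",
    "ForceMap",
    "AdhesionSet",
    "CellForceProfile",
    "compute_efficiency",
    "force_from_efficiency",
    "segment_adhesions",
    "profile_cell",
    "compare_groups_force",
    "match_adhesions",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone force -> FRET-efficiency calibration, piecewise linear.

    Forces (pN) must be strictly increasing starting at 0; efficiencies must
    be strictly decreasing (stretching the sensor lowers FRET).  Inversion is
    exact at the nodes and linear between them; efficiencies outside the
    calibrated range clamp to force 0 or ``f_max``.
    """

    forces: np.ndarray
    efficiencies: np.ndarray
    name: str = "user"

    def __post_init__(self):
        forces = np.asarray(self.forces, dtype=float).ravel()
        eff = np.asarray(self.efficiencies, dtype=float).ravel()
        if forces.size != eff.size or forces.size < 2:
            raise ValueError("calibration needs >= 2 (force, efficiency) pairs")
        if not np.all(np.diff(forces) > 0):
            raise ValueError("calibration forces must be strictly increasing")
        if not np.all(np.diff(eff) < 0):
            raise ValueError("calibration efficiencies must be strictly decreasing")
        if forces[0] < 0:
            raise ValueError("calibration forces must start at >= 0")
        object.__setattr__(self, "forces", forces)
        object.__setattr__(self, "efficiencies", eff)

    @property
    def f_max(self) -> float:
        return float(self.forces[-1])

    def efficiency_at(self, force):
        """Efficiency for a given force, clamped to the calibrated range."""
        return np.interp(force, self.forces, self.efficiencies)

    def force_at(self, efficiency):
        """Inverse map: force for a given efficiency (clamped at both ends)."""
        # np.interp needs ascending x; efficiencies are descending.
        return np.interp(
            efficiency, self.efficiencies[::-1], self.forces[::-1]
        )

    @classmethod
    def from_csv(cls, path, name=None) -> "CalibrationCurve":
        """Read a 2-column (force_pN, efficiency) CSV with a header row."""
        tbl = pd.read_csv(path)
        return cls(tbl.iloc[:, 0].to_numpy(), tbl.iloc[:, 1].to_numpy(),
                   name=name or str(path))

    @classmethod
    def default_synthetic(cls) -> "CalibrationCurve":
        """A 6-node synthetic calibration for tests and demos.

        0 pN -> 0.90 down to 10 pN -> 0.15, linear in between.  This curve is
        synthetic — packaged so the pipeline is exercisable without a
        measured sensor calibration — and is not a measured property of any
        real sensor construct.
        """
        return cls(
            np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0]),
            np.array([0.90, 0.75, 0.60, 0.45, 0.30, 0.15]),
            name="synthetic-default",
        )


@dataclass
class EfficiencyMap:
    """Per-pixel FRET efficiency with a validity mask.

    ``values`` is NaN on invalid pixels; valid pixels satisfy 0 <= E <= 1.
    """

    values: np.ndarray
    valid: np.ndarray
    pixel_size: float = 1.0


@dataclass
class ForceMap:
    """Per-pixel force (pN) derived from an EfficiencyMap via a calibration."""

    values: np.ndarray
    valid: np.ndarray
    pixel_size: float = 1.0
    calibration: str = "unknown"


@dataclass
class AdhesionSet:
    """Labeled adhesion regions and their per-region statistics.

    ``labels`` is an integer image (0 = background); ``table`` has one row
    per adhesion: label, cell_id, area_px, area_um2, mean_force_pN,
    mean_efficiency, centroid_row, centroid_col.
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size: float = 1.0
    cell_ids: frozenset = frozenset()

    def __len__(self):
        return len(self.table)


@dataclass(frozen=True)
class CellForceProfile:
    """Force summary for one cell.

    ``average_force_pN`` is ``None`` (absent), not 0, when the cell has no
    adhesions — a cell that produces no measurable force has no adhesion
    force to average.
    """

    cell_id: object
    n_adhesions: int
    force_producing: bool
    average_force_pN: object  # float | None
    total_area_um2: float


def compute_efficiency(
    donor,
    acceptor,
    bg_donor=0.0,
    bg_acceptor=0.0,
    bleedthrough=0.0,
    detection_ratio=1.0,
    intensity_floor=0.0,
    pixel_size=1.0,
) -> EfficiencyMap:
    """Per-pixel FRET efficiency from a donor/acceptor image pair.

    E = A' / (A' + gamma * D'), clamped to [0, 1]; pixels with corrected
    total intensity D' + A' below ``intensity_floor`` (or a non-positive
    denominator) are invalid.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError(
            f"donor {donor.shape} and acceptor {acceptor.shape} shapes differ"
        )
    if bleedthrough < 0:
        raise ValueError("bleedthrough must be >= 0")
    if detection_ratio <= 0:
        raise ValueError("detection_ratio must be > 0")
    d = donor - bg_donor
    a = acceptor - bg_acceptor - bleedthrough * d
    total = d + a
    denom = a + detection_ratio * d
    valid = (total >= intensity_floor) & (denom > 0)
    values = np.full(donor.shape, np.nan)
    np.divide(a, denom, out=values, where=valid)
    np.clip(values, 0.0, 1.0, out=values)
    values[~valid] = np.nan
    if not valid.any():
        warnings.warn("no pixel exceeds the intensity floor; all invalid",
                      stacklevel=2)
    return EfficiencyMap(values, valid, pixel_size)


def force_from_efficiency(emap: EfficiencyMap, cal: CalibrationCurve) -> ForceMap:
    """Invert the calibration pixel-wise: efficiency map -> force map (pN).

    Monotone piecewise-linear inversion; E above the zero-force efficiency
    clamps to 0 pN, E below the full-scale efficiency clamps to ``f_max``.
    """
    values = np.full(emap.values.shape, np.nan)
    values[emap.valid] = cal.force_at(emap.values[emap.valid])
    return ForceMap(values, emap.valid.copy(), emap.pixel_size, cal.name)


def _split_by_watershed(candidate, force, min_seed_separation, seed_prominence):
    """Split touching candidate components along force ridge lines.

    Seeds are the h-maxima of a lightly smoothed force map — maxima standing
    at least ``seed_prominence`` pN above their surroundings — so shot noise
    inside one adhesion does not spawn spurious seeds and a flat-topped
    adhesion yields a single connected seed region.  Seed regions whose
    centroids lie closer than ``min_seed_separation`` px are merged.  The
    watershed floods the negated (unsmoothed) force map so basins grow from
    high-force peaks outwards.
    """
    from skimage.morphology import h_maxima

    smoothed = ndi.gaussian_filter(np.nan_to_num(force, nan=0.0), 1.0)
    smoothed[~candidate] = 0.0
    peaks = h_maxima(smoothed, seed_prominence).astype(bool) & candidate
    markers = cc_label(peaks, connectivity=2)
    n = markers.max()
    if n == 0:
        return cc_label(candidate, connectivity=2)
    if n > 1 and min_seed_separation > 0:
        cents = np.array(ndi.center_of_mass(peaks, markers, range(1, n + 1)))
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(cents[i] - cents[j]) < min_seed_separation:
                    parent[find(i)] = find(j)
        remap = np.zeros(n + 1, dtype=np.int32)
        roots = {}
        for i in range(n):
            r = find(i)
            remap[i + 1] = roots.setdefault(r, len(roots) + 1)
        markers = remap[markers]
    return watershed(
        -np.nan_to_num(force, nan=0.0), markers, mask=candidate, connectivity=2
    )


def segment_adhesions(
    fmap: ForceMap,
    cellmask,
    force_threshold,
    min_area,
    split=True,
    min_seed_separation=3,
    seed_prominence=0.5,
    efficiency_map: EfficiencyMap | None = None,
) -> AdhesionSet:
    """Segment force-producing adhesions from a force map.

    Candidate pixels are valid, inside the cell mask, and above the force
    threshold.  Connected components (8-connectivity) smaller than
    ``min_area`` (um^2) are discarded; with ``split`` enabled, touching
    components are divided by watershed on the negated force map seeded at
    local force maxima.

    ``cellmask`` may be boolean or an integer label image assigning pixels to
    cells; each adhesion is attributed to the cell owning the majority of its
    pixels.
    """
    cellmask = np.asarray(cellmask)
    if cellmask.shape != fmap.values.shape:
        raise ValueError("cell mask shape must match the force map")
    if min_area <= 0:
        raise ValueError("min_area must be > 0")
    candidate = fmap.valid & (cellmask > 0) & (
        np.nan_to_num(fmap.values, nan=-np.inf) > force_threshold
    )
    if split:
        labels = _split_by_watershed(
            candidate, fmap.values, min_seed_separation, seed_prominence
        )
    else:
        labels = cc_label(candidate, connectivity=2)

    px_area = fmap.pixel_size**2
    rows = []
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area_px = int(mask.sum())
        if area_px == 0 or area_px * px_area < min_area:
            continue
        next_label += 1
        out[mask] = next_label
        rr, cc = np.nonzero(mask)
        if cellmask.dtype == bool:
            cell_id = 1
        else:
            ids, counts = np.unique(cellmask[mask], return_counts=True)
            cell_id = int(ids[np.argmax(counts)])
        mean_eff = (
            float(np.nanmean(efficiency_map.values[mask]))
            if efficiency_map is not None
            else float("nan")
        )
        rows.append(
            {
                "label": next_label,
                "cell_id": cell_id,
                "area_px": area_px,
                "area_um2": area_px * px_area,
                "mean_force_pN": float(fmap.values[mask].mean()),
                "mean_efficiency": mean_eff,
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "cell_id", "area_px", "area_um2", "mean_force_pN",
            "mean_efficiency", "centroid_row", "centroid_col",
        ],
    )
    if cellmask.dtype == bool:
        cell_ids = frozenset({1}) if cellmask.any() else frozenset()
    else:
        cell_ids = frozenset(int(v) for v in np.unique(cellmask) if v > 0)
    return AdhesionSet(out, table, fmap.pixel_size, cell_ids)


def profile_cell(adhesions: AdhesionSet, cell_id, weighting="pixel") -> CellForceProfile:
    """Summarize one cell's adhesions.

    ``weighting="pixel"`` averages force over all the cell's adhesion pixels
    (each pixel counts once); ``"adhesion"`` averages the per-adhesion mean
    forces unweighted.  A cell with no adhesions is reported as
    non-force-producing with an absent (None) average force.

    The cell must exist in the adhesion set's cell universe: unknown ids
    raise rather than silently returning an empty profile.
    """
    if weighting not in ("pixel", "adhesion"):
        raise ValueError("weighting must be 'pixel' or 'adhesion'")
    if cell_id not in adhesions.cell_ids and cell_id not in set(
        adhesions.table["cell_id"]
    ):
        raise KeyError(f"unknown cell_id {cell_id!r}")
    sub = adhesions.table[adhesions.table["cell_id"] == cell_id]
    if sub.empty:
        return CellForceProfile(cell_id, 0, False, None, 0.0)
    if weighting == "pixel":
        avg = float(
            (sub["mean_force_pN"] * sub["area_px"]).sum() / sub["area_px"].sum()
        )
    else:
        avg = float(sub["mean_force_pN"].mean())
    return CellForceProfile(
        cell_id,
        len(sub),
        True,
        avg,
        float(sub["area_um2"].sum()),
    )


def match_adhesions(adhesions: AdhesionSet, reference_labels, iou_threshold=0.5):
    """Match detected adhesions to reference (ground-truth) regions by IoU.

    Greedy one-to-one matching: each reference region pairs with the
    detected label of highest intersection-over-union, accepted when IoU >=
    ``iou_threshold`` and the detected label is still unclaimed.

    Returns a dict with ``pairs`` (DataFrame: reference_id, detected_label,
    iou), ``precision`` and ``recall``.
    """
    ref = np.asarray(reference_labels)
    det = adhesions.labels
    if ref.shape != det.shape:
        raise ValueError("label images must share a shape")
    pairs = []
    claimed = set()
    ref_ids = [int(v) for v in np.unique(ref) if v > 0]
    det_areas = {
        int(row["label"]): int(row["area_px"])
        for _, row in adhesions.table.iterrows()
    }
    # visit larger reference regions first so greedy claiming is stable
    ref_ids.sort(key=lambda i: -(ref == i).sum())
    for rid in ref_ids:
        rmask = ref == rid
        overlapping, counts = np.unique(det[rmask], return_counts=True)
        best_iou, best = 0.0, None
        for lab, inter in zip(overlapping, counts):
            if lab <= 0 or int(lab) in claimed:
                continue
            union = rmask.sum() + det_areas.get(int(lab), (det == lab).sum()) - inter
            iou = inter / union
            if iou > best_iou:
                best_iou, best = float(iou), int(lab)
        if best is not None and best_iou >= iou_threshold:
            claimed.add(best)
            pairs.append({"reference_id": rid, "detected_label": best,
                          "iou": best_iou})
    pairs = pd.DataFrame(pairs, columns=["reference_id", "detected_label", "iou"])
    n_ref = len(ref_ids)
    n_det = len(adhesions)
    return {
        "pairs": pairs,
        "precision": len(pairs) / n_det if n_det else float("nan"),
        "recall": len(pairs) / n_ref if n_ref else float("nan"),
    }


def compare_groups_force(
    profiles: pd.DataFrame,
    group_col="group",
    animal_col="animal",
    include_nonproducing_as_zero=False,
) -> dict:
    """Compare per-animal force and force-producing prevalence between groups.

    ``profiles`` needs one row per cell with columns ``average_force_pN``
    (NaN/None for non-producing cells), ``force_producing``, the group label,
    and the animal id.  Per-animal mean average-force is compared by a
    two-tailed Mann-Whitney test on animal means; the proportion of
    force-producing cells is compared by a two-sided Fisher exact test on the
    pooled cell counts.

    By default only force-producing cells enter the force average (the
    average force of a cell with no adhesions is undefined); set
    ``include_nonproducing_as_zero`` to count them as 0 pN instead.
    """
    profiles = pd.DataFrame(profiles)
    groups = list(pd.unique(profiles[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (profiles[group_col] == g).sum() == 0:
            raise ValueError(f"group {g!r} has no cells")
    g1, g2 = groups[:2]

    force = profiles.copy()
    force["average_force_pN"] = pd.to_numeric(
        force["average_force_pN"], errors="coerce"
    )
    if include_nonproducing_as_zero:
        force["average_force_pN"] = force["average_force_pN"].fillna(0.0)
    else:
        force = force.dropna(subset=["average_force_pN"])
    animal_means = (
        force.groupby([group_col, animal_col])["average_force_pN"]
        .mean()
        .reset_index()
    )
    mwu = mann_whitney_two_tailed(
        animal_means.loc[animal_means[group_col] == g1, "average_force_pN"],
        animal_means.loc[animal_means[group_col] == g2, "average_force_pN"],
    )

    fp = profiles["force_producing"].astype(bool)
    a = int((fp & (profiles[group_col] == g1)).sum())
    b = int(((~fp) & (profiles[group_col] == g1)).sum())
    c = int((fp & (profiles[group_col] == g2)).sum())
    d = int(((~fp) & (profiles[group_col] == g2)).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        # every cell (or none) force-producing in both groups: no
        # association is testable and the table carries no evidence
        fisher = GroupComparison(
            "fisher-exact", float("nan"), 1.0, (a + b, c + d),
            "degenerate (zero margin)",
        )
    else:
        fisher = fisher_exact_two_sided(a, b, c, d)

    return {
        "groups": (g1, g2),
        "force_mwu": mwu,
        "prevalence_fisher": fisher,
        "prevalence": {
            g1: a / (a + b) if a + b else float("nan"),
            g2: c / (c + d) if c + d else float("nan"),
        },
        "animal_means": animal_means,
    }
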