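"""Synthetic inputs with known ground truth for every analysis stage.

Every quantification stage in this package can be exercised without any
microscope or sequencer: this module forward-simulates

* two-channel tension-sensor images — per-pixel true FRET efficiency at the
  resting value everywhere except inside elliptical adhesions, where the
  calibration curve maps each adhesion's force to its efficiency; expected
  photon counts are ``donor = S(1-E) + B`` and ``acceptor = S·E + B`` with
  Poisson shot noise (no camera read noise);
* persistent-random-walk migration tracks — an Ornstein-Uhlenbeck velocity
  process whose stationary mean measured speed equals the requested speed;
* Bernoulli cell retention for detachment assays;
* niche sections — cells placed at sampled distances from a ventricle-border
  polyline with marker flags per group;
* negative-binomial count matrices with a gene-set fold-change in one group.

All randomness flows through :func:`numpy.random.default_rng` (PCG64); the
seed is carried in the outputs, and a fixed seed reproduces every output
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import CalibrationCurve

__all__ = [
    "SimConfig",
    "TensionImageSet",
    "SectionGeometry",
    "simulate_tension_images",
    "simulate_tracks",
    "simulate_detachment",
    "simulate_section",
    "simulate_counts",
]


@dataclass
class SimConfig:
    """Shared imaging-simulation parameters.

    ``pixel_size`` defaults to 0.16 um/px, typical of a x100 TIRF objective
    on an sCMOS camera.  ``sensor_photons`` is the mean total (donor +
    acceptor) signal per pixel; ``background_photons`` the mean offset per
    channel.  ``resting_efficiency`` must lie inside the calibration range.
    With ``noise`` enabled (default) images are Poisson photon counts;
    disabled, they are the exact expected values as floats.
    """

    seed: int = 0
    image_shape: tuple = (512, 512)
    pixel_size: float = 0.16
    background_photons: float = 100.0
    sensor_photons: float = 2000.0
    resting_efficiency: float = 0.90
    calibration: CalibrationCurve = field(
        default_factory=CalibrationCurve.default_synthetic
    )
    noise: bool = True

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.background_photons < 0 or self.sensor_photons <= 0:
            raise ValueError("photon budgets must be positive")
        lo = float(self.calibration.efficiencies.min())
        hi = float(self.calibration.efficiencies.max())
        if not (lo <= self.resting_efficiency <= hi):
            raise ValueError(
                f"resting_efficiency {self.resting_efficiency} outside the "
                f"calibration range [{lo}, {hi}]"
            )


@dataclass
class TensionImageSet:
    """Simulated tension-sensor field of view with ground truth.

    ``ground_truth`` has one row per adhesion (cell_id, adhesion_id, force,
    efficiency, centroid, semi-axes, orientation, area); ``gt_labels`` is the
    exact pixel mask per adhesion (values match ``adhesion_id``).
    """

    donor: np.ndarray
    acceptor: np.ndarray
    cell_mask: np.ndarray
    ground_truth: pd.DataFrame
    gt_labels: np.ndarray
    true_efficiency: np.ndarray
    config: SimConfig


def _ellipse_pixels(shape, center, axes, theta):
    """Pixel-center rasterization of an ellipse; exact, no anti-aliasing."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _draw(dist, rng):
    """Draw one value from a scalar, callable, or frozen distribution."""
    if callable(dist):
        return dist(rng)
    if hasattr(dist, "rvs"):
        return float(dist.rvs(random_state=rng))
    return float(dist)


def simulate_tension_images(
    config: SimConfig,
    n_cells: int,
    adhesions_per_cell=3,
    force_distribution=5.0,
    cell_radius_um=6.0,
    adhesion_semi_axes_um=((0.5, 1.2), (0.4, 0.6)),
    min_separation_um=0.5,
    max_retries=200,
) -> TensionImageSet:
    """Simulate a donor/acceptor tension-sensor image pair with ground truth.

    Cells are disks laid out on a grid; each receives
    ``adhesions_per_cell`` elliptical adhesions (an int, a callable of the
    rng, or a frozen distribution) at forces drawn from
    ``force_distribution``.  Adhesions are rejected and resampled when they
    would leave the cell footprint or come within ``min_separation_um`` of
    an existing adhesion (focal adhesions are discrete complexes; enforcing
    separation keeps the ground truth resolvable); after ``max_retries``
    failures the simulation errors out.

    The sensor coats the whole substrate, so the efficiency is the resting
    value outside adhesions (including outside cells); the cell mask is
    reported separately, as a segmentation stage would supply it.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_shape)
    px = config.pixel_size
    r_px = cell_radius_um / px

    # grid layout with enough clearance that cells never touch
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / n_cols))
    spacing_r = shape[0] / n_rows
    spacing_c = shape[1] / n_cols
    if min(spacing_r, spacing_c) < 2 * r_px + 4:
        raise ValueError(
            f"{n_cells} cells of radius {cell_radius_um} um do not fit in "
            f"a {shape} image at {px} um/px"
        )

    cell_mask = np.zeros(shape, dtype=np.int32)
    centers = []
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for i in range(n_cells):
        cr = (i // n_cols + 0.5) * spacing_r
        ccen = (i % n_cols + 0.5) * spacing_c
        centers.append((cr, ccen))
        cell_mask[(rr - cr) ** 2 + (cc - ccen) ** 2 <= r_px**2] = i + 1

    efficiency = np.full(shape, config.resting_efficiency)
    gt_labels = np.zeros(shape, dtype=np.int32)
    rows = []
    adhesion_id = 0
    (a_lo, a_hi), (b_lo, b_hi) = adhesion_semi_axes_um
    for cell_id, (cr, ccen) in enumerate(centers, start=1):
        n_adh = int(round(_draw(adhesions_per_cell, rng)))
        for _ in range(n_adh):
            placed = False
            for _attempt in range(max_retries):
                a_um = rng.uniform(a_lo, a_hi)
                b_um = rng.uniform(b_lo, min(b_hi, a_um))
                theta = rng.uniform(0, np.pi)
                rho = np.sqrt(rng.uniform(0, 1)) * (r_px - a_um / px - 1)
                phi = rng.uniform(0, 2 * np.pi)
                center = (cr + rho * np.sin(phi), ccen + rho * np.cos(phi))
                mask = _ellipse_pixels(shape, center, (a_um / px, b_um / px), theta)
                if not mask.any():
                    continue
                sep_px = min_separation_um / px
                halo = _ellipse_pixels(
                    shape, center,
                    (a_um / px + sep_px, b_um / px + sep_px), theta,
                )
                inside = cell_mask[mask] == cell_id
                clear = gt_labels[halo] == 0
                if inside.all() and clear.all():
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place an adhesion inside cell {cell_id} "
                    f"after {max_retries} attempts"
                )
            force = max(0.0, _draw(force_distribution, rng))
            adhesion_id += 1
            eff = float(config.calibration.efficiency_at(force))
            efficiency[mask] = eff
            gt_labels[mask] = adhesion_id
            rows.append(
                {
                    "adhesion_id": adhesion_id,
                    "cell_id": cell_id,
                    "force_pN": force,
                    "efficiency": eff,
                    "centroid_row": center[0],
                    "centroid_col": center[1],
                    "semi_axis_a_um": a_um,
                    "semi_axis_b_um": b_um,
                    "orientation_rad": theta,
                    "area_px": int(mask.sum()),
                    "area_um2": float(mask.sum() * px**2),
                }
            )

    s, b = config.sensor_photons, config.background_photons
    donor_mean = s * (1.0 - efficiency) + b
    acceptor_mean = s * efficiency + b
    if config.noise:
        donor = rng.poisson(donor_mean).astype(np.int64)
        acceptor = rng.poisson(acceptor_mean).astype(np.int64)
    else:
        donor, acceptor = donor_mean, acceptor_mean

    gt = pd.DataFrame(
        rows,
        columns=[
            "adhesion_id", "cell_id", "force_pN", "efficiency",
            "centroid_row", "centroid_col", "semi_axis_a_um",
            "semi_axis_b_um", "orientation_rad", "area_px", "area_um2",
        ],
    )
    return TensionImageSet(
        donor, acceptor, cell_mask, gt, gt_labels, efficiency, config
    )


def _ou_step_speed_factor(persistence_time, dt, n_sub):
    """Ratio of the per-frame step-averaged speed scale to the stationary one.

    Sampling positions every ``dt`` averages the velocity over the interval;
    for an OU process observed at ``n_sub`` substeps the variance of the
    time-averaged velocity is the stationary variance times
    ``(1/n^2) * sum_{i,j} rho^{|i-j|}`` with ``rho = exp(-dt/(n*tau))``.
    """
    rho = np.exp(-dt / (n_sub * persistence_time))
    idx = np.arange(n_sub)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return float(np.sqrt(corr.sum()) / n_sub)


def simulate_tracks(
    n_cells,
    mean_speed,
    persistence_time,
    dt,
    duration,
    positional_noise=0.0,
    seed=0,
    n_substeps=10,
    extent=None,
) -> pd.DataFrame:
    """Persistent-random-walk detection table (cell_id, frame, t, x, y).

    Velocities follow a 2-D Ornstein-Uhlenbeck process with relaxation time
    ``persistence_time``; the per-component stationary scale is calibrated so
    that the mean *measured* frame-to-frame speed (step length / dt, which a
    tracker computes from the sampled positions) equals ``mean_speed``.
    ``positional_noise`` adds independent Gaussian localization error (um) to
    every recorded position.  Starting positions are uniform over a square
    field of ``extent`` um per side; by default the field scales with the
    cell count (60 um mean spacing, a sparse plating density at which
    neighboring cells stay distinguishable to a tracker).
    """
    if n_cells <= 0 or dt <= 0 or duration < dt or persistence_time <= 0:
        raise ValueError("n_cells, dt, duration, persistence_time must be positive")
    if mean_speed < 0 or positional_noise < 0:
        raise ValueError("mean_speed and positional_noise must be >= 0")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt)) + 1
    h = dt / n_substeps
    # per-component stationary sd for a half-normal speed mean of mean_speed,
    # corrected for averaging the velocity over the sampling interval
    factor = _ou_step_speed_factor(persistence_time, dt, n_substeps)
    sd = mean_speed / (np.sqrt(np.pi / 2.0) * factor) if mean_speed > 0 else 0.0
    a = np.exp(-h / persistence_time)
    kick = sd * np.sqrt(1 - a**2)

    if extent is None:
        extent = 60.0 * np.sqrt(n_cells)
    pos = rng.uniform(0, extent, size=(n_cells, 2))
    vel = rng.normal(0, sd, size=(n_cells, 2)) if sd > 0 else np.zeros((n_cells, 2))
    records = np.empty((n_cells * n_frames, 5))
    for frame in range(n_frames):
        obs = pos
        if positional_noise > 0:
            obs = pos + rng.normal(0, positional_noise, size=pos.shape)
        block = slice(frame * n_cells, (frame + 1) * n_cells)
        records[block, 0] = np.arange(n_cells)
        records[block, 1] = frame
        records[block, 2] = frame * dt
        records[block, 3:] = obs
        if frame == n_frames - 1:
            break
        for _ in range(n_substeps):
            if sd > 0:
                vel = vel * a + kick * rng.normal(size=vel.shape)
            pos = pos + vel * h
    df = pd.DataFrame(records, columns=["cell_id", "frame", "t", "x", "y"])
    df["cell_id"] = df["cell_id"].astype(int)
    df["frame"] = df["frame"].astype(int)
    return df.sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)


def simulate_detachment(n_before, p_retain, seed=0, extent=(1000.0, 1000.0)):
    """Bernoulli retention: (before, after) coordinate tables.

    Each of ``n_before`` uniformly placed cells survives dissociation
    independently with probability ``p_retain``; the after table is the
    retained subset of the before table (same ids and positions).
    """
    if not 0 <= p_retain <= 1:
        raise ValueError("p_retain must be in [0, 1]")
    if n_before <= 0:
        raise ValueError("n_before must be > 0")
    rng = np.random.default_rng(seed)
    before = pd.DataFrame(
        {
            "cell_id": np.arange(n_before),
            "x": rng.uniform(0, extent[0], n_before),
            "y": rng.uniform(0, extent[1], n_before),
        }
    )
    retained = rng.random(n_before) < p_retain
    return before, before.loc[retained].reset_index(drop=True)


@dataclass
class SectionGeometry:
    """A simulated 2-D section: cells, ventricle border, region polygons."""

    cells: pd.DataFrame
    border: np.ndarray  # polyline vertices (n, 2) um
    regions: dict


def _distance_sampler(dist):
    """Normalize a distance spec into a callable rng -> float >= 0.

    Accepts a constant, a (mean, sd) pair (gamma-distributed, exact mean),
    a frozen scipy distribution, or a callable.
    """
    if callable(dist):
        return dist
    if hasattr(dist, "rvs"):
        return lambda rng: float(dist.rvs(random_state=rng))
    if np.isscalar(dist):
        return lambda rng: float(dist)
    mean, sd = dist
    if mean < 0:
        raise ValueError("distance mean must be >= 0")
    if sd == 0 or mean == 0:
        return lambda rng: float(mean)
    shape_k = (mean / sd) ** 2
    scale = sd**2 / mean
    return lambda rng: float(rng.gamma(shape_k, scale))


def simulate_section(
    n_per_group,
    distance_distributions,
    border_polyline,
    region_polygons=None,
    marker_scheme=None,
    seed=0,
    animals_per_group=1,
) -> SectionGeometry:
    """Place cells at known distances from a ventricle-border polyline.

    Each group's cells sit at distances drawn from its distribution,
    offset perpendicular to a uniformly random point along the border; the
    recorded ``true_distance`` is recomputed against the full polyline so it
    is exact even near corners.  ``marker_scheme`` maps group -> dict of
    boolean marker flags stamped on every cell of the group; animal ids
    cycle within each group.
    """
    from .niche import distance_to_border, make_polyline

    border = np.asarray(border_polyline, dtype=float)
    line = make_polyline(border)
    rng = np.random.default_rng(seed)
    marker_scheme = marker_scheme or {}
    length = line.length
    rows = []
    for group, n in n_per_group.items():
        sampler = _distance_sampler(distance_distributions[group])
        for i in range(n):
            d = sampler(rng)
            u = rng.uniform(0, length)
            p0 = np.asarray(line.interpolate(u).coords[0])
            eps = min(1e-3 * max(length, 1.0), length / 2)
            pa = np.asarray(line.interpolate(max(0.0, u - eps)).coords[0])
            pb = np.asarray(line.interpolate(min(length, u + eps)).coords[0])
            tangent = pb - pa
            norm = np.linalg.norm(tangent)
            tangent = tangent / norm if norm > 0 else np.array([1.0, 0.0])
            normal = np.array([-tangent[1], tangent[0]])
            xy = p0 + d * normal
            row = {
                "x": xy[0],
                "y": xy[1],
                "group": group,
                "animal": f"{group}-{i % animals_per_group}",
                "sampled_distance": d,
                "true_distance": distance_to_border(xy, line),
            }
            row.update({k: bool(v) for k, v in marker_scheme.get(group, {}).items()})
            rows.append(row)
    cells = pd.DataFrame(rows)
    return SectionGeometry(cells, border, dict(region_polygons or {}))


def simulate_counts(
    n_per_group,
    n_genes,
    gene_set,
    log_fold_effect=0.0,
    dispersion=0.3,
    seed=0,
    mean_log_expression=0.5,
):
    """Negative-binomial count matrix with a gene-set effect in one group.

    ``n_per_group`` maps group label -> number of cells; the *last* group in
    iteration order (conventionally ``"old"``) has the gene-set genes' means
    scaled by ``exp(log_fold_effect)``.  ``gene_set`` is either a list of
    gene names (``g0000``-style) or an int taken as the first k genes.
    Per-gene base means are log-normal; counts have variance
    ``mu + dispersion * mu**2`` (Poisson at dispersion 0).

    Returns ``(counts, labels, gene_set_names)``: a cells x genes integer
    DataFrame, a Series of group labels, and the resolved gene-set list.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    if isinstance(gene_set, int):
        if gene_set > n_genes:
            raise ValueError("gene_set size exceeds n_genes")
        gene_set = genes[:gene_set]
    unknown = set(gene_set) - set(genes)
    if unknown:
        raise ValueError(f"gene_set members not simulated: {sorted(unknown)}")
    base_mean = rng.lognormal(mean_log_expression, 1.0, size=n_genes)
    in_set = np.isin(genes, list(gene_set))
    groups = list(n_per_group)
    effect_group = groups[-1]

    blocks, labels, index = [], [], []
    for group, n in n_per_group.items():
        mu = np.tile(base_mean, (n, 1))
        if group == effect_group and log_fold_effect != 0.0:
            mu[:, in_set] *= np.exp(log_fold_effect)
        if dispersion == 0:
            counts = rng.poisson(mu)
        else:
            n_param = 1.0 / dispersion
            p = n_param / (n_param + mu)
            counts = rng.negative_binomial(n_param, p)
        blocks.append(counts)
        labels.extend([group] * n)
        index.extend(f"{group}_{i}" for i in range(n))
    counts = pd.DataFrame(
        np.vstack(blocks), index=index, columns=genes, dtype=np.int64
    )
    return counts, pd.Series(labels, index=index, name="group"), list(gene_set)
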