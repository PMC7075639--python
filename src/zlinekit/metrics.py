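"""Scalar z-line architecture metrics and report assembly.

* orientational order parameter (OOP) — max eigenvalue of the mean nematic
  tensor of an angle set; 1 = perfectly aligned, 0 = isotropic;
* normalized stress estimate σ̃x along the cell's major axis — each z-line
  pixel contributes the squared x-component of the force direction
  perpendicular to it;
* sarcomere spacing — dominant z-line repeat distance along the local actin
  director;
* nuclei density per coverslip area.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .angles import orientation_tensor
from .types import BinarySkeleton, DirectorGrid, GrayImage, MetricsReport

__all__ = [
    "oop",
    "estimate_stress",
    "sarcomere_spacing",
    "count_nuclei",
    "nuclei_density",
    "aggregate_report",
]


def oop(angles: Sequence[float] | np.ndarray) -> float:
    """Orientational order parameter of a set of nematic angles.

    The maximum eigenvalue of T = ⟨2 r rᵀ − I⟩ over the unit pseudo-vectors
    r = (cos θ, sin θ); equals 1 for identical angles and 0 for an isotropic
    distribution.  NaN (missing) for an empty input.
    """
    angles = np.asarray(angles, dtype=float).ravel()
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        warnings.warn("OOP undefined for an empty angle set")
        return float("nan")
    return float(np.linalg.eigvalsh(orientation_tensor(angles))[-1])


def estimate_stress(zline_angles: Sequence[float] | np.ndarray,
                    n_z: int | None = None, n_total: int = 0) -> float:
    """Normalized stress σ̃x produced along the major (x) axis of a cell.

    Each sarcomere pushes perpendicular to its z-line, so a z-line pixel of
    orientation θ_i contributes cos²(θ_i + π/2) to the x-directed force:

        σ̃x = Σ_i cos²(θ_i + π/2) / N_T

    with N_T the total pixel count of the cell area.  Input images are
    assumed aligned with the major axis along x; rotate the angles first if
    not.  Bounded by 0 ≤ σ̃x ≤ N_z / N_T.
    """
    zline_angles = np.asarray(zline_angles, dtype=float).ravel()
    if n_z is None:
        n_z = zline_angles.size
    if n_z != zline_angles.size:
        raise ValueError("N_z must equal the number of z-line angles")
    if n_total <= 0:
        raise ValueError("N_T must be positive")
    if n_z > n_total:
        raise ValueError("N_z cannot exceed N_T")
    return float(np.sum(np.cos(zline_angles + np.pi / 2.0) ** 2) / n_total)


def sarcomere_spacing(zline_skeleton: BinarySkeleton, grid: DirectorGrid,
                      max_spacing_um: float = 5.0,
                      min_pixels_per_grid: int = 8,
                      peak_prominence_frac: float = 0.3) -> np.ndarray:
    """Distribution of z-line repeat distances (sarcomere lengths), in μm.

    Within each usable director-grid tile, z-line pixel positions are
    projected onto the local actin director; pixels of one z-line collapse
    to nearly one projection value, so the histogram of pairwise projected
    separations peaks at multiples of the sarcomere spacing.  The first
    off-origin peak of that (autocorrelation-like) histogram is the tile's
    dominant spacing.  Tiles with too few pixels or no stable peak are
    skipped; the pooled per-tile spacings are returned.
    """
    if grid.image_shape != zline_skeleton.shape:
        raise ValueError("grid does not match the skeleton shape")
    res = zline_skeleton.resolution
    coords = zline_skeleton.coordinates()
    if len(coords) == 0:
        return np.array([])
    ti, tj = grid.tile_index(coords[:, 0], coords[:, 1])
    spacings = []
    max_sep_px = max_spacing_um * res
    for i, j in {(int(a), int(b)) for a, b in zip(ti, tj)}:
        if not grid.usable[i, j]:
            continue
        sel = (ti == i) & (tj == j)
        pts = coords[sel]
        if len(pts) < min_pixels_per_grid:
            continue
        th = grid.theta[i, j]
        # math frame projection: x = col, y = -row
        proj = pts[:, 1] * np.cos(th) - pts[:, 0] * np.sin(th)
        sep = np.abs(proj[:, None] - proj[None, :])[np.triu_indices(len(proj), k=1)]
        sep = sep[sep <= max_sep_px]
        if sep.size == 0:
            continue
        counts, edges = np.histogram(sep, bins=np.arange(0, max_sep_px + 1.0, 1.0))
        # skip the origin cluster (pixels of the same z-line, ±2 px wide)
        peaks, _ = find_peaks(counts, prominence=peak_prominence_frac * counts.max())
        peaks = peaks[peaks >= 3]
        # a genuine lattice peak towers over the typical bin; scattered
        # points give a flat pairwise histogram and are skipped
        typical = max(float(np.median(counts[3:])), 1.0)
        peaks = peaks[counts[peaks] >= 3.0 * typical]
        if peaks.size == 0:
            continue
        centers = 0.5 * (edges[:-1] + edges[1:])
        spacings.append(centers[peaks[0]] / res)
    return np.asarray(spacings)


def count_nuclei(nuclei_image: GrayImage, blur_sigma: float = 2.0,
                 min_area_px: int = 20, min_peak_distance_px: int = 5) -> int:
    """Count nuclei in a DAPI-like channel.

    Gaussian blur → Otsu global threshold → hole filling → watershed split
    of touching blobs seeded at distance-transform maxima → count of
    components at or above the area floor.  A blank image counts zero.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops
    from skimage.segmentation import watershed

    pix = ndimage.gaussian_filter(nuclei_image.pixels, blur_sigma)
    if np.ptp(pix) == 0:
        return 0
    mask = pix > threshold_otsu(pix)
    if not mask.any():
        return 0
    mask = ndimage.binary_fill_holes(mask)
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(distance, min_distance=min_peak_distance_px, labels=mask)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask) if len(peaks) else label(mask)
    return sum(1 for rp in regionprops(labels) if rp.area >= min_area_px)


def nuclei_density(nuclei_counts: Sequence[int], field_areas_mm2: Sequence[float]) -> float:
    """Nuclei per mm²: total count over all fields of view / total area."""
    counts = np.asarray(nuclei_counts, dtype=float)
    areas = np.asarray(field_areas_mm2, dtype=float)
    if counts.shape != areas.shape:
        raise ValueError("counts and areas must have equal length")
    if counts.size == 0:
        warnings.warn("nuclei density undefined without fields")
        return float("nan")
    if np.any(areas <= 0):
        raise ValueError("field areas must be positive")
    return float(counts.sum() / areas.sum())


def aggregate_report(per_field: Sequence[MetricsReport]) -> MetricsReport:
    """Pool per-field reports into one per-coverslip report.

    Every metric is recomputed from the pooled raw data — concatenated angle
    lists for the OOPs, summed N_z/N_α for the z-line fraction, pooled line
    lengths for the median, summed counts over summed areas for nuclei —
    because medians and tensor eigenvalues do not average.
    """
    if len(per_field) == 0:
        raise ValueError("aggregate_report requires at least one field")
    resolutions = {r.resolution for r in per_field}
    if len(resolutions) > 1:
        raise ValueError("cannot pool fields with inconsistent resolutions")

    z_angles = np.concatenate([np.atleast_1d(r.zline_angles) for r in per_field]) \
        if any(np.size(r.zline_angles) for r in per_field) else np.array([])
    a_angles = np.concatenate([np.atleast_1d(r.aactinin_angles) for r in per_field]) \
        if any(np.size(r.aactinin_angles) for r in per_field) else np.array([])
    lengths = np.concatenate([np.atleast_1d(r.line_lengths_um) for r in per_field]) \
        if any(np.size(r.line_lengths_um) for r in per_field) else np.array([])
    n_z = int(sum(r.n_z for r in per_field))
    n_alpha = int(sum(r.n_alpha for r in per_field))
    n_total = int(sum(r.n_total for r in per_field))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled_zoop = oop(z_angles) if z_angles.size else float("nan")
        pooled_aoop = oop(a_angles) if a_angles.size else float("nan")
    fraction = n_z / n_alpha if n_alpha > 0 else float("nan")
    median_len = float(np.median(lengths)) if lengths.size else float("nan")
    sigma = estimate_stress(z_angles, n_total=n_total) if (z_angles.size and n_total) else float("nan")

    counted = [(r.nuclei_count, r.field_area_mm2) for r in per_field
               if np.isfinite(r.nuclei_count) and np.isfinite(r.field_area_mm2)]
    if counted:
        density = nuclei_density([c for c, _ in counted], [a for _, a in counted])
    else:
        density = float("nan")

    return MetricsReport(
        image_id="+".join(r.image_id for r in per_field if r.image_id),
        resolution=per_field[0].resolution,
        zline_oop=pooled_zoop,
        alpha_actinin_oop=pooled_aoop,
        zline_fraction=fraction,
        median_czl_um=median_len,
        n_z=n_z,
        n_alpha=n_alpha,
        n_total=n_total,
        sigma_x=sigma,
        nuclei_per_mm2=density,
        zline_angles=z_angles,
        aactinin_angles=a_angles,
        line_lengths_um=lengths,
        nuclei_count=float(sum(c for c, _ in counted)) if counted else float("nan"),
        field_area_mm2=float(sum(a for _, a in counted)) if counted else float("nan"),
    )
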