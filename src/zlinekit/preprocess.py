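"""α-actinin skeleton extraction and orientation estimation.

The preprocessing chain turns a raw α-actinin micrograph into (a) a
one-pixel-wide binary skeleton of the stained ridges and (b) a per-pixel
nematic orientation field:

    coherence-enhancing diffusion → white top-hat contrast enhancement →
    background surface removal → adaptive thresholding → thinning + trimming

Orientation is estimated from the diffusion-filtered image with the classic
least-mean-square (structure-tensor) gradient estimator used for fibrillar
and fingerprint-like imagery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, thin, white_tophat

from .angles import canonicalize
from .types import BinarySkeleton, GrayImage, OrientationField

__all__ = [
    "DiffusionParams",
    "diffuse",
    "tophat_enhance",
    "remove_background",
    "binarize_adaptive",
    "skeletonize_and_trim",
    "estimate_orientation",
    "actin_orientation",
    "PreprocessConfig",
    "extract_skeleton",
]

#: explicit-scheme stability bound for the divergence update (unit grid
#: spacing, diffusivities ≤ 1): dt ≤ 1 / (2 · ndim) = 0.25
MAX_TIME_STEP = 0.25


@dataclass
class DiffusionParams:
    """Parameters of coherence-enhancing anisotropic diffusion.

    time : total diffusion time (≥ 0); more time = smoother, more connected
        ridges, at the cost of merging close striations.
    sigma : Gaussian scale (px) for pre-smoothing before gradients.
    rho : Gaussian scale (px) for structure-tensor integration; should be of
        the order of the ridge length so that coherence is measured along
        whole striations.
    contrast : coherence contrast constant C in exp(-C / (μ1-μ2)²); larger C
        demands stronger coherence before diffusion aligns with the ridge.
    alpha : small isotropic floor keeping the diffusion tensor positive.
    time_step : explicit step size, bounded by `MAX_TIME_STEP`.
    """

    time: float = 5.0
    sigma: float = 1.0
    rho: float = 4.0
    contrast: float = 1e-6
    alpha: float = 1e-3
    time_step: float = 0.2

    def validate(self) -> None:
        if self.time < 0:
            raise ValueError("diffusion time must be >= 0")
        if self.sigma < 0 or self.rho < 0:
            raise ValueError("smoothing scales must be >= 0")
        if self.contrast <= 0:
            raise ValueError("contrast constant must be > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.time_step <= MAX_TIME_STEP):
            raise ValueError(
                f"time step must satisfy 0 < dt <= {MAX_TIME_STEP} "
                "(explicit-scheme stability bound)"
            )


def _diffusion_tensor(u: np.ndarray, sigma: float, rho: float,
                      contrast: float, alpha: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel diffusion tensor components (d11, d12, d22).

    Eigen-frame of the ρ-smoothed structure tensor; diffusivity α across the
    coherent direction and α + (1-α)·exp(-C/κ) along it, κ = (μ1-μ2)².
    """
    us = ndimage.gaussian_filter(u, sigma) if sigma > 0 else u
    gy, gx = np.gradient(us)
    j11 = ndimage.gaussian_filter(gx * gx, rho) if rho > 0 else gx * gx
    j12 = ndimage.gaussian_filter(gx * gy, rho) if rho > 0 else gx * gy
    j22 = ndimage.gaussian_filter(gy * gy, rho) if rho > 0 else gy * gy

    # closed-form eigen decomposition of the symmetric 2x2 field
    trace_half = 0.5 * (j11 + j22)
    root = np.sqrt(np.maximum(0.25 * (j11 - j22) ** 2 + j12 ** 2, 0.0))
    mu1 = trace_half + root      # dominant-gradient eigenvalue (across ridge)
    mu2 = trace_half - root
    kappa = (mu1 - mu2) ** 2

    lam1 = np.full_like(u, alpha)
    with np.errstate(divide="ignore"):
        lam2 = np.where(kappa > 0, alpha + (1 - alpha) * np.exp(-contrast / np.where(kappa > 0, kappa, 1.0)), alpha)

    # eigenvector v1 of the dominant eigenvalue; v2 perpendicular
    v1x = np.where(root > 0, j12, 1.0)
    v1y = np.where(root > 0, mu1 - j11, 0.0)
    norm = np.sqrt(v1x ** 2 + v1y ** 2)
    degenerate = norm < 1e-30
    v1x = np.where(degenerate, 1.0, v1x / np.where(degenerate, 1.0, norm))
    v1y = np.where(degenerate, 0.0, v1y / np.where(degenerate, 1.0, norm))

    d11 = lam1 * v1x ** 2 + lam2 * v1y ** 2
    d12 = (lam1 - lam2) * v1x * v1y
    d22 = lam1 * v1y ** 2 + lam2 * v1x ** 2
    return d11, d12, d22


def diffuse(image: GrayImage, params: DiffusionParams) -> GrayImage:
    """Coherence-enhancing anisotropic diffusion of a micrograph.

    Diffuses strongly along locally coherent ridge directions and barely
    across them, closing gaps in striations while preserving their edges.
    An explicit finite-difference scheme integrates ∂u/∂t = div(D ∇u) with
    the diffusion tensor D rebuilt from the structure tensor every step.
    """
    params.validate()
    if not np.all(np.isfinite(image.pixels)):
        raise ValueError("cannot diffuse non-finite image")
    if params.time == 0:
        return image.with_pixels(image.pixels.copy())

    scale = float(np.abs(image.pixels).max())
    if scale == 0:
        return image.with_pixels(image.pixels.copy())
    u = image.pixels / scale

    n_steps = int(np.ceil(params.time / params.time_step))
    dt = params.time / n_steps
    for _ in range(n_steps):
        d11, d12, d22 = _diffusion_tensor(u, params.sigma, params.rho,
                                          params.contrast, params.alpha)
        uy, ux = np.gradient(u)
        jx = d11 * ux + d12 * uy
        jy = d12 * ux + d22 * uy
        div = np.gradient(jy, axis=0) + np.gradient(jx, axis=1)
        u = u + dt * div
    out = np.clip(u * scale, 0.0, None)
    return image.with_pixels(out)


def isotropic_diffuse(image: GrayImage, time: float, time_step: float = 0.2) -> GrayImage:
    """Plain heat-equation diffusion with the same explicit scheme.

    Reference behaviour for the anisotropy of `diffuse`: it blurs equally in
    every direction, so a coherent ridge loses cross-ridge contrast faster
    than under coherence-enhanced diffusion at equal time.
    """
    if time < 0:
        raise ValueError("time must be >= 0")
    if not (0 < time_step <= MAX_TIME_STEP):
        raise ValueError("unstable time step")
    u = image.pixels.astype(float).copy()
    if time == 0:
        return image.with_pixels(u)
    n_steps = int(np.ceil(time / time_step))
    dt = time / n_steps
    for _ in range(n_steps):
        uy, ux = np.gradient(u)
        u = u + dt * (np.gradient(uy, axis=0) + np.gradient(ux, axis=1))
    return image.with_pixels(np.clip(u, 0.0, None))


def tophat_enhance(image: GrayImage, radius_px: float) -> GrayImage:
    """White top-hat contrast enhancement: image − morphological opening.

    Removes structures wider than the disk element (slowly varying
    background) while keeping thin bright striations.
    """
    if radius_px < 1:
        raise ValueError("top-hat radius must be >= 1 px")
    footprint = disk(int(round(radius_px)))
    if footprint.shape[0] > min(image.shape):
        raise ValueError("top-hat radius exceeds image size")
    out = white_tophat(image.pixels, footprint=footprint)
    return image.with_pixels(np.clip(out, 0.0, None))


def remove_background(image: GrayImage, grid_px: int = 32,
                      percentile: float = 10.0) -> GrayImage:
    """Subtract a smooth interpolated background surface.

    A low percentile of each `grid_px` block estimates the local background;
    a spline through the block estimates is subtracted and the result
    clipped at zero.
    """
    if grid_px < 8:
        raise ValueError("background grid must be >= 8 px")
    pix = image.pixels
    if np.ptp(pix) == 0:
        warnings.warn("degenerate (constant) image: background removal returns zeros")
        return image.with_pixels(np.zeros_like(pix))

    from scipy.interpolate import RectBivariateSpline

    h, w = pix.shape
    rows = np.arange(0, h, grid_px)
    cols = np.arange(0, w, grid_px)
    centers_r = np.minimum(rows + grid_px / 2.0, h - 1)
    centers_c = np.minimum(cols + grid_px / 2.0, w - 1)
    block = np.empty((len(rows), len(cols)))
    for i, r0 in enumerate(rows):
        for j, c0 in enumerate(cols):
            block[i, j] = np.percentile(pix[r0:r0 + grid_px, c0:c0 + grid_px], percentile)
    kx = min(3, len(centers_r) - 1)
    ky = min(3, len(centers_c) - 1)
    if kx == 0 or ky == 0:
        background = np.full_like(pix, block.mean())
    else:
        spline = RectBivariateSpline(centers_r, centers_c, block, kx=kx, ky=ky)
        background = spline(np.arange(h), np.arange(w))
    return image.with_pixels(np.clip(pix - background, 0.0, None))


def binarize_adaptive(image: GrayImage, window_px: int = 49,
                      offset: float = 0.0) -> np.ndarray:
    """Adaptive mean thresholding: true where intensity > local mean + offset."""
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    local_mean = ndimage.uniform_filter(image.pixels, size=window_px, mode="reflect")
    return image.pixels > local_mean + offset


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return ndimage.convolve(mask.astype(int), kernel, mode="constant")


def _prune_spurs(mask: np.ndarray, min_spur_px: int) -> np.ndarray:
    """Remove skeleton spur branches shorter than `min_spur_px`.

    From each endpoint, the path is traced until it reaches a branch point
    (> 2 neighbors); if the traced branch is shorter than the floor it is
    deleted.  Free-standing lines (no branch point) are never trimmed.
    """
    mask = mask.copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbor_count(mask)
        endpoints = np.argwhere(mask & (counts == 1))
        for r, c in endpoints:
            if not mask[r, c]:
                continue
            path = [(r, c)]
            prev = None
            cur = (r, c)
            hit_branch = False
            while len(path) <= min_spur_px:
                nbrs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if (dr or dc)
                    and 0 <= cur[0] + dr < mask.shape[0]
                    and 0 <= cur[1] + dc < mask.shape[1]
                    and mask[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) == 0:
                    break  # isolated stub; leave to the object-size floor
                if len(nbrs) > 1 or _neighbor_count(mask)[nbrs[0]] > 2:
                    hit_branch = True
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if hit_branch and len(path) < min_spur_px:
                for p in path:
                    mask[p] = False
                changed = True
    return mask


def skeletonize_and_trim(mask: np.ndarray, min_spur_px: int = 4,
                         min_object_px: int = 4,
                         resolution: float = 6.0) -> BinarySkeleton:
    """Thin a binary mask to 1-px width, prune short spurs, drop small objects."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty mask: returning empty skeleton")
        return BinarySkeleton(mask=np.zeros_like(mask), resolution=resolution)
    skel = thin(mask)
    if min_spur_px > 0:
        skel = _prune_spurs(skel, min_spur_px)
    if min_object_px > 1:
        labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_object_px
            keep[0] = False
            skel = keep[labels]
    return BinarySkeleton(mask=skel, resolution=resolution)


def estimate_orientation(image: GrayImage, window_px: int = 15,
                         energy_floor_frac: float = 0.01) -> OrientationField:
    """Least-mean-square structure orientation of ridges, per pixel.

    Image gradients are averaged as double-angle components over a window
    (the least-squares orientation fit); the structure (ridge) direction is
    the dominant gradient direction rotated by π/2, canonical in [0, π).
    Pixels whose windowed gradient energy falls below
    `energy_floor_frac · max(energy)` are marked invalid.

    Angles follow the package convention: counter-clockwise from the +x
    (column) axis in a y-up frame, so vertical stripes give θ = π/2.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    gy_raster, gx = np.gradient(image.pixels)
    gy = -gy_raster  # raster rows grow downward; flip to the y-up math frame
    gxx = ndimage.uniform_filter(gx * gx, window_px)
    gyy = ndimage.uniform_filter(gy * gy, window_px)
    gxy = ndimage.uniform_filter(gx * gy, window_px)
    energy = gxx + gyy
    floor = energy_floor_frac * energy.max() if energy.max() > 0 else np.inf
    valid = energy > max(floor, 0.0)
    phi = 0.5 * np.arctan2(2.0 * gxy, gxx - gyy)   # dominant gradient direction
    theta = canonicalize(phi + np.pi / 2.0)        # ridge runs perpendicular
    theta = np.where(valid, theta, np.nan)
    return OrientationField(theta=theta, valid=valid)


def actin_orientation(image: GrayImage, blur_sigma: float = 2.0,
                      window_px: int = 15,
                      energy_floor_frac: float = 0.01) -> OrientationField:
    """Orientation of actin fibrils.

    The actin channel is Gaussian-filtered and standardized to zero mean and
    unit standard deviation before the least-mean-square orientation fit.
    """
    pix = ndimage.gaussian_filter(image.pixels, blur_sigma)
    std = pix.std()
    if std == 0:
        return OrientationField(theta=np.full(image.shape, np.nan),
                                valid=np.zeros(image.shape, dtype=bool))
    norm = (pix - pix.mean()) / std
    shifted = GrayImage(pixels=norm - norm.min() + 0.0,
                        resolution=image.resolution, channel=image.channel)
    return estimate_orientation(shifted, window_px=window_px,
                                energy_floor_frac=energy_floor_frac)


@dataclass
class PreprocessConfig:
    """Resolved parameters of the α-actinin skeleton extraction chain."""

    diffusion: DiffusionParams = None  # type: ignore[assignment]
    tophat_radius_px: float = 3.0
    background_grid_px: int = 32
    background_percentile: float = 10.0
    threshold_window_px: int = 49     # ≈ 4 sarcomere spacings at 6 px/μm
    threshold_offset: float = 0.0
    min_spur_px: int = 4
    min_object_px: int = 4
    orientation_window_px: int = 9      # ≈ one z-line length at 6 px/μm
    orientation_energy_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.diffusion is None:
            self.diffusion = DiffusionParams()


def extract_skeleton(image: GrayImage,
                     config: PreprocessConfig | None = None
                     ) -> tuple[BinarySkeleton, OrientationField]:
    """Full preprocessing chain: raw α-actinin image → skeleton + orientations."""
    config = config or PreprocessConfig()
    smoothed = diffuse(image, config.diffusion)
    enhanced = tophat_enhance(smoothed, config.tophat_radius_px)
    flattened = remove_background(enhanced, config.background_grid_px,
                                  config.background_percentile)
    mask = binarize_adaptive(flattened, config.threshold_window_px,
                             config.threshold_offset)
    skeleton = skeletonize_and_trim(mask, config.min_spur_px,
                                    config.min_object_px,
                                    resolution=image.resolution)
    field = estimate_orientation(smoothed, config.orientation_window_px,
                                 config.orientation_energy_floor)
    return skeleton, field
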