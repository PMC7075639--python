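"""Core containers for the z-line analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Channel = Literal["alpha_actinin", "actin", "nuclei"]
SkeletonProvenance = Literal["raw_alpha_actinin", "zline_only"]

#: Nominal imaging resolution of the 40x acquisition regime, pixels per μm.
DEFAULT_RESOLUTION = 6.0


@dataclass
class GrayImage:
    """A single-channel grayscale micrograph.

    Parameters
    ----------
    pixels : 2-D float array of nonnegative, finite intensities.
    resolution : pixels per μm (> 0).
    channel : which stain the image carries.
    """

    pixels: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    channel: Channel = "alpha_actinin"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be nonnegative")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive (pixels per μm)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels=pixels, resolution=self.resolution, channel=self.channel)


@dataclass
class BinarySkeleton:
    """One-pixel-wide boolean ridge mask of an α-actinin image.

    ``provenance`` records whether the mask is the raw thinned α-actinin
    skeleton (whose true-pixel count is N_α) or the z-line-only skeleton
    left after actin-guided segmentation (count N_z).
    """

    mask: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    provenance: SkeletonProvenance = "raw_alpha_actinin"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("skeleton mask must be 2-D")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (row, col) true-pixel coordinates, row-major order."""
        return np.argwhere(self.mask)


@dataclass
class OrientationField:
    """Per-pixel nematic orientation θ ∈ [0, π) with a validity mask.

    Invalid pixels (flat windows, below the gradient-energy floor) carry NaN
    and must never be consumed downstream.
    """

    theta: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.theta.shape != self.valid.shape:
            raise ValueError("theta and valid must share a shape")
        ok = self.theta[self.valid]
        if ok.size and (np.any(~np.isfinite(ok)) or np.any(ok < 0) or np.any(ok >= np.pi)):
            raise ValueError("valid angles must be finite and in [0, π)")
        self.theta = np.where(self.valid, self.theta, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape


@dataclass
class DirectorGrid:
    """Local actin director per non-overlapping grid tile.

    Each ~5 μm tile holds the max-eigenvalue eigenvector (director) of the
    nematic structure tensor of the valid actin orientations it contains.
    """

    grid_px: int
    theta: np.ndarray        # per-tile director angle, NaN where undefined
    coherence: np.ndarray    # per-tile max eigenvalue of T, in [0, 1]
    populated: np.ndarray    # any valid actin pixel in the tile
    image_shape: tuple[int, int]

    #: tiles whose tensor max eigenvalue falls below this are degenerate
    DEGENERATE_EPS = 1e-9

    @property
    def degenerate(self) -> np.ndarray:
        return self.populated & (self.coherence < self.DEGENERATE_EPS)

    @property
    def usable(self) -> np.ndarray:
        """Tiles carrying a meaningful director."""
        return self.populated & ~self.degenerate

    def tile_index(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel coordinates to tile indices."""
        return np.asarray(rows) // self.grid_px, np.asarray(cols) // self.grid_px


@dataclass
class ContinuousLine:
    """One detected continuous z-line: an ordered 8-connected pixel path."""

    path: np.ndarray             # (n, 2) ordered (row, col)
    resolution: float

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int).reshape(-1, 2)
        if len(self.path) == 0:
            raise ValueError("a line needs at least one pixel")
        if len(self.path) > 1:
            steps = np.abs(np.diff(self.path, axis=0))
            if np.any(steps.max(axis=1) != 1):
                raise ValueError("consecutive path pixels must be 8-adjacent")

    @property
    def pixel_count(self) -> int:
        return len(self.path)

    @property
    def geometric_length_px(self) -> float:
        if len(self.path) < 2:
            return 0.0
        return float(np.sqrt((np.diff(self.path, axis=0) ** 2).sum(axis=1)).sum())

    @property
    def length_um(self) -> float:
        return self.geometric_length_px / self.resolution


@dataclass
class LineSet:
    """All continuous z-lines of one image; lines partition the z-line skeleton."""

    lines: list[ContinuousLine] = field(default_factory=list)
    resolution: float = DEFAULT_RESOLUTION
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.lines)

    def pixel_counts(self) -> np.ndarray:
        return np.array([ln.pixel_count for ln in self.lines], dtype=int)

    def lengths_um(self) -> np.ndarray:
        return np.array([ln.length_um for ln in self.lines], dtype=float)


@dataclass
class SegmentationResult:
    """Outcome of actin-guided segmentation of the α-actinin skeleton."""

    zline_skeleton: BinarySkeleton
    offtarget_mask: np.ndarray
    unassigned_mask: np.ndarray
    gamma_map: np.ndarray        # per-pixel γ ∈ [0,1] on assigned skeleton pixels, NaN elsewhere
    n_alpha: int
    n_z: int

    def __post_init__(self) -> None:
        if self.n_z > self.n_alpha:
            raise ValueError("N_z cannot exceed N_alpha")


@dataclass
class MetricsReport:
    """Per-image (or pooled per-coverslip) z-line architecture metrics.

    Scalar metrics are accompanied by the raw counts and angle/length pools
    they were computed from, so that coverslip aggregation can recompute
    every metric from raw data instead of averaging per-field scalars.
    Missing metrics are NaN, never 0.
    """

    image_id: str = ""
    resolution: float = DEFAULT_RESOLUTION
    zline_oop: float = np.nan
    alpha_actinin_oop: float = np.nan
    zline_fraction: float = np.nan
    median_czl_um: float = np.nan
    n_z: int = 0
    n_alpha: int = 0
    n_total: int = 0
    sigma_x: float = np.nan
    nuclei_per_mm2: float = np.nan
    # raw pools used for aggregation
    zline_angles: np.ndarray = field(default_factory=lambda: np.array([]))
    aactinin_angles: np.ndarray = field(default_factory=lambda: np.array([]))
    line_lengths_um: np.ndarray = field(default_factory=lambda: np.array([]))
    nuclei_count: float = np.nan
    field_area_mm2: float = np.nan

    def scalar_row(self) -> dict:
        """Flat dict of the scalar metrics, for CSV reports."""
        return {
            "image_id": self.image_id,
            "zline_oop": self.zline_oop,
            "aactinin_oop": self.alpha_actinin_oop,
            "zline_fraction": self.zline_fraction,
            "median_czl_um": self.median_czl_um,
            "n_z": self.n_z,
            "n_alpha": self.n_alpha,
            "sigma_x": self.sigma_x,
            "nuclei_per_mm2": self.nuclei_per_mm2,
        }
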