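"""Single-image and per-coverslip orchestration of the full analysis.

Per image: α-actinin preprocessing → (if an actin channel is present) actin
orientation, director grid and actin-guided segmentation → continuity
grouping → metrics.  Without an actin co-stain, z-lines cannot be told from
off-target staining, so only the plain α-actinin OOP is reported and the
z-line fraction is left missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as zio
from .config import RunConfig
from .continuity import detect_lines, median_czl
from .metrics import aggregate_report, count_nuclei, estimate_stress, oop
from .preprocess import actin_orientation, extract_skeleton
from .segmentation import compute_director_grid, segment_offtarget, zline_fraction
from .types import GrayImage, MetricsReport

log = logging.getLogger(__name__)


@dataclass
class ImageEntry:
    """One field of view in a batch manifest."""

    image_id: str
    coverslip_id: str = ""
    path_actinin: str = ""
    path_actin: str = ""
    path_nuclei: str = ""


@dataclass
class ImageResult:
    report: MetricsReport
    artifacts: dict


def analyze_image(actinin: GrayImage, actin: GrayImage | None = None,
                  nuclei: GrayImage | None = None,
                  config: RunConfig | None = None,
                  image_id: str = "") -> ImageResult:
    """Run the full pipeline on in-memory channels and assemble the report."""
    config = config or RunConfig()
    skeleton, skel_field = extract_skeleton(actinin, config.preprocess)
    coords = skeleton.coordinates()
    artifacts: dict = {"skeleton": skeleton, "orientation": skel_field}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a_angles = skel_field.theta[coords[:, 0], coords[:, 1]] if len(coords) else np.array([])
        a_angles = a_angles[np.isfinite(a_angles)]
        aactinin_oop = oop(a_angles) if a_angles.size else float("nan")

    report = MetricsReport(
        image_id=image_id,
        resolution=actinin.resolution,
        alpha_actinin_oop=aactinin_oop,
        aactinin_angles=a_angles,
        n_alpha=0,
        n_total=int(np.prod(actinin.shape)),
    )

    zskel, zline_angles = skeleton, a_angles
    if actin is not None:
        actin_field = actin_orientation(actin, blur_sigma=config.actin_blur_sigma,
                                        window_px=config.preprocess.orientation_window_px)
        grid = compute_director_grid(actin_field, config.grid_um, actinin.resolution)
        seg = segment_offtarget(skeleton, skel_field, grid, config.gamma_threshold)
        zskel = seg.zline_skeleton
        zc = zskel.coordinates()
        zline_angles = skel_field.theta[zc[:, 0], zc[:, 1]] if len(zc) else np.array([])
        zline_angles = zline_angles[np.isfinite(zline_angles)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.zline_fraction = zline_fraction(seg)
            report.zline_oop = oop(zline_angles) if zline_angles.size else float("nan")
        report.n_alpha = seg.n_alpha
        report.n_z = seg.n_z
        report.zline_angles = zline_angles
        if report.n_total > 0 and zline_angles.size:
            shifted = zline_angles - np.deg2rad(config.major_axis_deg)
            report.sigma_x = estimate_stress(shifted, n_total=report.n_total)
        artifacts.update(segmentation=seg, director_grid=grid, actin_orientation=actin_field)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lines = detect_lines(zskel, skel_field)
        report.median_czl_um = median_czl(lines, config.czl_min_pixels)
    qualifying = np.array([ln.length_um for ln in lines.lines
                           if ln.pixel_count >= config.czl_min_pixels])
    report.line_lengths_um = qualifying
    artifacts["lines"] = lines

    area_mm2 = config.field_area_mm2
    if area_mm2 is None:
        h, w = actinin.shape
        area_mm2 = (h / actinin.resolution / 1000.0) * (w / actinin.resolution / 1000.0)
    if nuclei is not None:
        report.nuclei_count = float(count_nuclei(nuclei))
        report.field_area_mm2 = area_mm2
        report.nuclei_per_mm2 = report.nuclei_count / area_mm2

    return ImageResult(report=report, artifacts=artifacts)


def run_image(config: RunConfig, entry: ImageEntry,
              out_dir: str | Path | None = None) -> ImageResult:
    """Analyze one manifest entry from disk, optionally writing artifacts."""
    actinin = zio.read_image(entry.path_actinin, config.resolution, "alpha_actinin")
    actin = zio.read_image(entry.path_actin, config.resolution, "actin") \
        if entry.path_actin else None
    nuclei = zio.read_image(entry.path_nuclei, config.resolution, "nuclei") \
        if entry.path_nuclei else None
    result = analyze_image(actinin, actin, nuclei, config, image_id=entry.image_id)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = entry.image_id or Path(entry.path_actinin).stem
        zio.write_mask(out / f"{stem}_skeleton.png", result.artifacts["skeleton"])
        if "segmentation" in result.artifacts:
            seg = result.artifacts["segmentation"]
            zio.write_mask(out / f"{stem}_zline.png", seg.zline_skeleton)
            zio.write_mask(out / f"{stem}_offtarget.png", seg.offtarget_mask)
            zio.write_gamma_map(out / f"{stem}_gamma.tif", seg.gamma_map)
        zio.write_line_labels(out / f"{stem}_lines.png", result.artifacts["lines"],
                              result.artifacts["skeleton"].shape)
        zio.lines_table(result.artifacts["lines"]).to_csv(
            out / f"{stem}_lines.csv", index=False)
    return result


def run_coverslip(config: RunConfig, entries: list[ImageEntry],
                  out_dir: str | Path | None = None
                  ) -> tuple[MetricsReport, list[MetricsReport], list[str]]:
    """Analyze all fields of a coverslip and pool them into one report.

    Individual failures are logged and skipped; the batch continues.
    Returns (pooled report, per-field reports, failed image ids).
    """
    if not entries:
        raise ValueError("a coverslip needs at least one field of view")
    reports, failed = [], []
    for entry in entries:
        try:
            reports.append(run_image(config, entry, out_dir).report)
        except Exception as exc:  # noqa: BLE001 — batch isolation is the contract
            log.error("field %s failed: %s", entry.image_id, exc)
            failed.append(entry.image_id)
    if not reports:
        raise RuntimeError("every field of the coverslip failed")
    return aggregate_report(reports), reports, failed


def read_manifest(path: str | Path) -> dict[str, list[ImageEntry]]:
    """Read a batch manifest CSV into entries grouped by coverslip.

    Columns: coverslip_id, field_id, path_actinin, path_actin, path_nuclei
    (blank = channel absent).  Paths are resolved relative to the manifest.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"coverslip_id", "field_id", "path_actinin"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = path.parent

    def resolve(p: str) -> str:
        return str(base / p) if p and not Path(p).is_absolute() else p

    groups: dict[str, list[ImageEntry]] = {}
    for _, row in df.iterrows():
        entry = ImageEntry(
            image_id=row["field_id"],
            coverslip_id=row["coverslip_id"],
            path_actinin=resolve(row["path_actinin"]),
            path_actin=resolve(row.get("path_actin", "")),
            path_nuclei=resolve(row.get("path_nuclei", "")),
        )
        groups.setdefault(entry.coverslip_id, []).append(entry)
    return groups
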