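"""Per-reader, per-slice discrepancy reports against the consensus.

For every slice key shared by a reader and the consensus, the report
measures the distance from each reader contour point to the consensus
polyline (segment-wise minimum, not vertex-only), flags points farther
than a threshold (default 3 mm), summarizes the distances (mean, max, SD),
and builds a cross-reader band: on a fixed fan of directions from the
consensus centroid, the min/max radial position of all readers' contours.
Keys the reader contoured but for which no consensus exists (e.g. too few
readers) are skipped and listed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import LinearRing, LineString, Point

from .contour_model import Contour, StudyContourSet


@dataclass
class SliceDiscrepancy:
    """Distances, flags, band and summary for one slice key."""

    frame: str
    slice_index: int
    surface: str
    reader_contour: Contour
    consensus_contour: Contour
    distances_mm: np.ndarray
    flagged: np.ndarray
    band_angles_deg: np.ndarray
    band_min_mm: np.ndarray
    band_max_mm: np.ndarray
    mean_mm: float
    max_mm: float
    sd_mm: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.frame, self.slice_index, self.surface)


def point_to_contour_distance(point, contour: Contour) -> float:
    """Minimum Euclidean distance from a point to the closed polyline."""
    ring = LinearRing(contour.points)
    return float(Point(point).distance(ring))


def _radial_extent(ring: LinearRing, origin: np.ndarray, angle_rad: float,
                   reach: float) -> float:
    """Outermost crossing radius of the ray from origin; nan if no crossing."""
    direction = np.array([np.cos(angle_rad), np.sin(angle_rad)])
    ray = LineString([origin, origin + reach * direction])
    hit = ray.intersection(ring)
    if hit.is_empty:
        return float("nan")
    origin_pt = Point(origin)
    pieces = getattr(hit, "geoms", [hit])
    return max(
        max(origin_pt.distance(Point(c)) for c in np.asarray(g.coords))
        for g in pieces
    )


def discrepancy_report(
    reader: StudyContourSet,
    consensus: StudyContourSet,
    all_readers: Sequence[StudyContourSet],
    threshold_mm: float = 3.0,
    n_directions: int = 72,
) -> tuple[list[SliceDiscrepancy], list[tuple[str, int, str]]]:
    """Discrepancy of one reader against the consensus over shared keys.

    Returns (per-slice discrepancies, skipped keys) where skipped keys are
    those the reader contoured without a consensus counterpart.
    """
    shared = sorted(set(reader.contours) & set(consensus.contours))
    skipped = sorted(set(reader.contours) - set(consensus.contours))
    angles = np.linspace(0.0, 360.0, n_directions, endpoint=False)
    out = []
    for key in shared:
        frame, s, surface = key
        reader_contour = reader.contours[key]
        consensus_contour = consensus.contours[key]
        ring = LinearRing(consensus_contour.points)
        pts = shapely.points(reader_contour.points)
        distances = np.asarray(shapely.distance(pts, ring), dtype=float)
        flagged = np.flatnonzero(distances > threshold_mm)

        origin = consensus_contour.centroid
        others = [rs.contours[key] for rs in all_readers if key in rs.contours]
        reach = 10.0 + max(
            (float(np.hypot(*(c.points - origin).T).max()) for c in others),
            default=10.0,
        )
        rings = [LinearRing(c.points) for c in others]
        band_min = np.full(n_directions, np.nan)
        band_max = np.full(n_directions, np.nan)
        for d, ang in enumerate(np.deg2rad(angles)):
            radii = [_radial_extent(r, origin, ang, reach) for r in rings]
            radii = [r for r in radii if np.isfinite(r)]
            if radii:
                band_min[d] = min(radii)
                band_max[d] = max(radii)

        out.append(SliceDiscrepancy(
            frame=frame, slice_index=s, surface=surface,
            reader_contour=reader_contour,
            consensus_contour=consensus_contour,
            distances_mm=distances, flagged=flagged,
            band_angles_deg=angles, band_min_mm=band_min, band_max_mm=band_max,
            mean_mm=float(distances.mean()),
            max_mm=float(distances.max()),
            sd_mm=float(distances.std()),
        ))
    return out, skipped


def write_discrepancy_csv(discrepancies: Sequence[SliceDiscrepancy], path) -> None:
    """Per-point distance table: key, point_index, distance_mm, flagged."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "slice_index", "surface", "point_index",
                         "distance_mm", "flagged"])
        for d in discrepancies:
            flagged = set(d.flagged.tolist())
            for i, dist in enumerate(d.distances_mm):
                writer.writerow([d.frame, d.slice_index, d.surface, i,
                                 repr(float(dist)), int(i in flagged)])


def render_report(
    discrepancies: Sequence[SliceDiscrepancy],
    pdf_path,
    csv_path=None,
    title: Optional[str] = None,
) -> dict:
    """Draw the per-slice report (consensus, reader, band, flags) to a PDF.

    The underlying numbers always go to a CSV next to the figure (or to
    ``csv_path``) so the report is testable without pixel comparison.  An
    empty discrepancy list yields a CSV with a header and no figure pages
    (no PDF file is created).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    pdf_path = str(pdf_path)
    if csv_path is None:
        csv_path = pdf_path.rsplit(".", 1)[0] + ".csv"
    write_discrepancy_csv(discrepancies, csv_path)
    written = {"csv": str(csv_path)}
    if not discrepancies:
        return written

    with PdfPages(pdf_path) as pdf:
        for d in discrepancies:
            fig, ax = plt.subplots(figsize=(5, 5))
            origin = d.consensus_contour.centroid
            ok = np.isfinite(d.band_min_mm) & np.isfinite(d.band_max_mm)
            if ok.any():
                ang = np.deg2rad(d.band_angles_deg[ok])
                outer = origin + np.column_stack(
                    [d.band_max_mm[ok] * np.cos(ang), d.band_max_mm[ok] * np.sin(ang)])
                inner = origin + np.column_stack(
                    [d.band_min_mm[ok] * np.cos(ang), d.band_min_mm[ok] * np.sin(ang)])
                band = np.vstack([outer, inner[::-1]])
                ax.fill(band[:, 0], band[:, 1], color="magenta", alpha=0.25,
                        lw=0, label="reader range")
            cpts = np.vstack([d.consensus_contour.points,
                              d.consensus_contour.points[:1]])
            rpts = np.vstack([d.reader_contour.points, d.reader_contour.points[:1]])
            ax.plot(cpts[:, 0], cpts[:, 1], "r-", lw=1.5, label="consensus")
            ax.plot(rpts[:, 0], rpts[:, 1], "g-", lw=1.2, label="reader")
            if len(d.flagged):
                fl = d.reader_contour.points[d.flagged]
                ax.plot(fl[:, 0], fl[:, 1], "kv", ms=6, label="> threshold")
            ax.set_aspect("equal")
            ax.invert_yaxis()  # image-style orientation
            head = f"{d.frame} slice {d.slice_index} {d.surface}"
            if title:
                head = f"{title} - {head}"
            ax.set_title(
                f"{head}\nmean {d.mean_mm:.2f} mm, max {d.max_mm:.2f} mm, "
                f"SD {d.sd_mm:.2f} mm"
            )
            ax.legend(loc="upper right", fontsize=7)
            pdf.savefig(fig)
            plt.close(fig)
    written["pdf"] = pdf_path
    return written
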