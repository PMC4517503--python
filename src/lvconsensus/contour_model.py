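"""Domain types and geometry for short-axis LV contour analysis.

Contours are closed planar polygons in physical millimetre coordinates,
one per (frame, slice, surface) key.  The pixel grid convention places the
centre of pixel (row 0, col 0) at (dx/2, dy/2), so a point (x_mm, y_mm)
lives on a continuous image plane of extent ``n_cols*dx`` by ``n_rows*dy``.
Slice index 0 is the most apical contoured slice.

Rasterization produces a supersampled binary decision map (default 4x the
pixel grid): a cell is foreground iff its centre is inside the polygon
under the even-odd rule, with a half-open boundary convention so that cells
whose centre falls exactly on an edge are resolved deterministically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from shapely.geometry import LinearRing, MultiPolygon, Polygon
from skimage import measure

FRAMES = ("ED", "ES")
SURFACES = ("endo", "epi")

#: column order of the contour exchange format
EXCHANGE_FIELDS = (
    "case_id",
    "source_id",
    "frame",
    "slice_index",
    "surface",
    "point_index",
    "x_mm",
    "y_mm",
)


class ContourParseError(ValueError):
    """Malformed contour exchange file."""


class ContourValidationError(ValueError):
    """Contour or contour-set invariant violated."""


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class SliceGeometry:
    """Short-axis stack geometry: in-plane pixel size, slice spacing, extent.

    ``slice_spacing_mm`` is the centre-to-centre distance between adjacent
    slices (may exceed the thickness for gapped acquisitions; contiguous
    stacks have spacing == thickness).
    """

    pixel_size_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_spacing_mm: float
    n_rows: int
    n_cols: int
    n_slices: int

    def __post_init__(self) -> None:
        dx, dy = self.pixel_size_mm
        if not (dx > 0 and dy > 0):
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_mm}")
        if self.slice_thickness_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("slice thickness and spacing must be positive")
        if min(self.n_rows, self.n_cols, self.n_slices) < 1:
            raise ValueError("image dimensions must be positive integers")

    @property
    def width_mm(self) -> float:
        return self.n_cols * self.pixel_size_mm[0]

    @property
    def height_mm(self) -> float:
        return self.n_rows * self.pixel_size_mm[1]


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of an implicitly closed polygon (CCW positive)."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(eq=False)
class Contour:
    """One closed polygon for one surface on one slice at one frame.

    Points are stored counter-clockwise (normalized on construction); the
    polygon is implicitly closed and must be simple with nonzero area.
    """

    surface: str
    frame: str
    slice_index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ContourValidationError(f"unknown surface {self.surface!r}")
        if self.frame not in FRAMES:
            raise ContourValidationError(f"unknown frame {self.frame!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourValidationError(
                f"points must be an (n, 2) array, got shape {pts.shape}"
            )
        if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ContourValidationError(
                f"polygon needs >= 3 points ({self.frame}, slice "
                f"{self.slice_index}, {self.surface})"
            )
        if not np.isfinite(pts).all():
            raise ContourValidationError("non-finite contour coordinates")
        area = signed_area(pts)
        if area == 0.0:
            raise ContourValidationError(
                f"degenerate polygon with zero area ({self.frame}, slice "
                f"{self.slice_index}, {self.surface})"
            )
        if area < 0:
            pts = pts[::-1].copy()
        try:
            simple = LinearRing(pts).is_simple
        except Exception as exc:  # shapely rejects badly degenerate rings
            raise ContourValidationError(
                f"invalid polygon ({self.frame}, slice {self.slice_index}, "
                f"{self.surface}): {exc}"
            ) from exc
        if not simple:
            raise ContourValidationError(
                f"self-intersecting polygon ({self.frame}, slice "
                f"{self.slice_index}, {self.surface})"
            )
        self.points = pts

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.frame, self.slice_index, self.surface)

    @property
    def centroid(self) -> np.ndarray:
        c = Polygon(self.points).centroid
        return np.array([c.x, c.y])

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.surface, self.frame, self.slice_index,
                       self.points + np.array([dx, dy]))

    def equals(self, other: "Contour", tol: float = 0.0) -> bool:
        if self.key != other.key or len(self.points) != len(other.points):
            return False
        if tol == 0.0:
            return bool(np.array_equal(self.points, other.points))
        return bool(np.allclose(self.points, other.points, atol=tol))


def polygon_area_mm2(contour: Contour) -> float:
    """Absolute shoelace area of the contour polygon, mm^2."""
    return abs(signed_area(contour.points))


# ---------------------------------------------------------------------------
# contour sets


@dataclass
class StudyContourSet:
    """All contours for one case from one source (reader, truth, consensus).

    Keys are (frame, slice_index, surface); any key may be absent (readers
    are free to skip slices).  Invariants checked on insertion: points lie
    within the image bounds, at most one contour per key, and on any ED
    slice holding both surfaces the endocardial area is smaller than the
    epicardial area.
    """

    case_id: str
    source_id: str
    geometry: SliceGeometry
    contours: dict[tuple[str, int, str], Contour] = field(default_factory=dict)

    def add(self, contour: Contour) -> None:
        key = contour.key
        if key in self.contours:
            raise ContourValidationError(
                f"duplicate contour for key {key} in {self.case_id}/{self.source_id}"
            )
        pts = contour.points
        tol = 1e-9
        if (pts[:, 0].min() < -tol or pts[:, 1].min() < -tol
                or pts[:, 0].max() > self.geometry.width_mm + tol
                or pts[:, 1].max() > self.geometry.height_mm + tol):
            raise ContourValidationError(
                f"contour outside image bounds for key {key} in "
                f"{self.case_id}/{self.source_id}"
            )
        frame, s, surface = key
        if frame == "ED":
            other = self.contours.get(("ED", s, "epi" if surface == "endo" else "endo"))
            if other is not None:
                endo, epi = (contour, other) if surface == "endo" else (other, contour)
                if polygon_area_mm2(endo) >= polygon_area_mm2(epi):
                    raise ContourValidationError(
                        f"endo area >= epi area on ED slice {s} in "
                        f"{self.case_id}/{self.source_id}"
                    )
        self.contours[key] = contour

    def get(self, frame: str, slice_index: int, surface: str) -> Optional[Contour]:
        return self.contours.get((frame, slice_index, surface))

    def keys(self) -> list[tuple[str, int, str]]:
        return sorted(self.contours.keys())

    def slices_with(self, frame: str, surface: str) -> list[int]:
        return sorted(s for (f, s, srf) in self.contours if f == frame and srf == surface)

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self) -> Iterator[Contour]:
        for key in self.keys():
            yield self.contours[key]

    def equals(self, other: "StudyContourSet", tol: float = 0.0) -> bool:
        if (self.case_id, self.source_id, self.geometry) != (
                other.case_id, other.source_id, other.geometry):
            return False
        if set(self.contours) != set(other.contours):
            return False
        return all(self.contours[k].equals(other.contours[k], tol=tol)
                   for k in self.contours)


# ---------------------------------------------------------------------------
# exchange format I/O
#
# One text record per point: case_id,source_id,frame,slice_index,surface,
# point_index,x_mm,y_mm -- header line first, points in CCW order, plus a
# geometry comment line so a file round-trips without side information.


def _geometry_comment(geom: SliceGeometry) -> str:
    dx, dy = geom.pixel_size_mm
    return ("# geometry "
            f"{dx!r} {dy!r} {geom.slice_thickness_mm!r} {geom.slice_spacing_mm!r} "
            f"{geom.n_rows} {geom.n_cols} {geom.n_slices}")


def _parse_geometry_comment(line: str) -> SliceGeometry:
    parts = line.split()
    if len(parts) != 9:
        raise ContourParseError(f"malformed geometry comment: {line!r}")
    vals = parts[2:]
    return SliceGeometry(
        pixel_size_mm=(float(vals[0]), float(vals[1])),
        slice_thickness_mm=float(vals[2]),
        slice_spacing_mm=float(vals[3]),
        n_rows=int(vals[4]), n_cols=int(vals[5]), n_slices=int(vals[6]),
    )


def write_contour_set(cs: StudyContourSet, path) -> None:
    """Write a contour set in the exchange format (UTF-8, LF, CCW points)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_geometry_comment(cs.geometry) + "\n")
        fh.write(",".join(EXCHANGE_FIELDS) + "\n")
        for contour in cs:
            frame, s, surface = contour.key
            for i, (x, y) in enumerate(contour.points):
                fh.write(f"{cs.case_id},{cs.source_id},{frame},{s},{surface},"
                         f"{i},{float(x)!r},{float(y)!r}\n")


def read_contour_set(path, geometry: Optional[SliceGeometry] = None) -> StudyContourSet:
    """Read one contour set from an exchange file.

    The file's geometry comment is used unless ``geometry`` is given
    explicitly.  Parse errors name the offending line; validation errors
    name the (case, source, frame, slice, surface).
    """
    records: dict[tuple[str, int, str], list[tuple[int, float, float]]] = {}
    case_id = source_id = None
    file_geometry = None
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                if row[0].startswith("# geometry"):
                    file_geometry = _parse_geometry_comment(",".join(row))
                continue
            if not header_seen:
                if [c.strip() for c in row] != list(EXCHANGE_FIELDS):
                    raise ContourParseError(
                        f"{path}: line {lineno}: bad header {row!r}"
                    )
                header_seen = True
                continue
            if len(row) != len(EXCHANGE_FIELDS):
                raise ContourParseError(
                    f"{path}: line {lineno}: expected {len(EXCHANGE_FIELDS)} "
                    f"fields, got {len(row)}"
                )
            try:
                cid, sid, frame, s, surface, pidx, x, y = row
                s = int(s)
                pidx = int(pidx)
                x = float(x)
                y = float(y)
            except ValueError as exc:
                raise ContourParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            if case_id is None:
                case_id, source_id = cid, sid
            elif (cid, sid) != (case_id, source_id):
                raise ContourParseError(
                    f"{path}: line {lineno}: mixed case/source "
                    f"({cid},{sid}) vs ({case_id},{source_id})"
                )
            records.setdefault((frame, s, surface), []).append((pidx, x, y))
    if case_id is None:
        raise ContourParseError(f"{path}: no contour records found")
    geom = geometry or file_geometry
    if geom is None:
        raise ContourParseError(
            f"{path}: no geometry comment in file and none supplied"
        )
    cs = StudyContourSet(case_id=case_id, source_id=source_id, geometry=geom)
    for (frame, s, surface), pts in sorted(records.items()):
        pts.sort(key=lambda t: t[0])
        arr = np.array([(x, y) for _, x, y in pts], dtype=float)
        try:
            cs.add(Contour(surface=surface, frame=frame, slice_index=s, points=arr))
        except ContourValidationError as exc:
            raise ContourValidationError(
                f"{case_id}/{source_id} ({frame}, slice {s}, {surface}): {exc}"
            ) from exc
    return cs


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class BinaryMask:
    """Supersampled binary decision map for one slice/surface/frame."""

    slice_index: int
    surface: str
    frame: str
    factor: int
    grid: np.ndarray
    cell_area_mm2: float

    def area_mm2(self) -> float:
        return float(self.grid.sum()) * self.cell_area_mm2


def rasterize(contour: Contour, geometry: SliceGeometry, factor: int = 4) -> BinaryMask:
    """Rasterize a contour to a supersampled binary mask.

    A cell is 1 iff its centre is inside the polygon under the even-odd
    rule; boundary-touching centres are resolved by the half-open
    convention (an edge claims rows with y_lo <= y_c < y_hi, and the
    strict ``x_c < x_edge`` test keeps left edges in, right edges out).
    """
    if factor < 1:
        raise ValueError("supersampling factor must be >= 1")
    dx, dy = geometry.pixel_size_mm
    pts = contour.points
    tol = 1e-9
    if (pts[:, 0].min() < -tol or pts[:, 1].min() < -tol
            or pts[:, 0].max() > geometry.width_mm + tol
            or pts[:, 1].max() > geometry.height_mm + tol):
        raise ContourValidationError(
            f"contour outside image bounds ({contour.frame}, slice "
            f"{contour.slice_index}, {contour.surface})"
        )
    cw, ch = dx / factor, dy / factor
    n_rows_s, n_cols_s = geometry.n_rows * factor, geometry.n_cols * factor
    r0 = max(0, int(np.floor(pts[:, 1].min() / ch)))
    r1 = min(n_rows_s, int(np.ceil(pts[:, 1].max() / ch)) + 1)
    c0 = max(0, int(np.floor(pts[:, 0].min() / cw)))
    c1 = min(n_cols_s, int(np.ceil(pts[:, 0].max() / cw)) + 1)
    grid = np.zeros((n_rows_s, n_cols_s), dtype=bool)
    if r1 > r0 and c1 > c0:
        ys = (np.arange(r0, r1) + 0.5) * ch
        xs = (np.arange(c0, c1) + 0.5) * cw
        sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        nxt = np.roll(pts, -1, axis=0)
        for (x1, y1), (x2, y2) in zip(pts, nxt):
            if y1 == y2:
                continue
            ylo, yhi = (y1, y2) if y1 < y2 else (y2, y1)
            i0 = int(np.searchsorted(ys, ylo, side="left"))
            i1 = int(np.searchsorted(ys, yhi, side="left"))
            if i0 >= i1:
                continue
            yr = ys[i0:i1]
            xint = x1 + (yr - y1) * (x2 - x1) / (y2 - y1)
            sub[i0:i1, :] ^= xs[None, :] < xint[:, None]
        grid[r0:r1, c0:c1] = sub
    return BinaryMask(
        slice_index=contour.slice_index,
        surface=contour.surface,
        frame=contour.frame,
        factor=factor,
        grid=grid,
        cell_area_mm2=cw * ch,
    )


# ---------------------------------------------------------------------------
# contour extraction from a probability map


def extract_contour(
    prob_map: np.ndarray,
    geometry: SliceGeometry,
    factor: int = 4,
    threshold: float = 0.5,
    frame: str = "ED",
    slice_index: int = 0,
    surface: str = "endo",
    simplify_tol: Optional[float] = None,
) -> Optional[Contour]:
    """Boundary polygon of the largest connected component of {W >= threshold}.

    The boundary is traced at supersampled resolution (marching squares on
    the thresholded map) and converted to mm.  Returns None when the
    thresholded set is empty ("no contour", not an error).
    """
    prob = np.asarray(prob_map, dtype=float)
    binary = prob >= threshold
    if not binary.any():
        return None
    labels = measure.label(binary, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(counts.argmax())
    rows = np.flatnonzero(comp.any(axis=1))
    cols = np.flatnonzero(comp.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    padded = np.pad(comp[r0:r1 + 1, c0:c1 + 1].astype(float), 1)
    traces = measure.find_contours(padded, 0.5)
    if not traces:  # pragma: no cover - nonempty component always traces
        return None
    best = max(traces, key=lambda t: abs(signed_area(t[:, ::-1])))
    coords = best - 1.0 + np.array([r0, c0])
    dx, dy = geometry.pixel_size_mm
    x = (coords[:, 1] + 0.5) * dx / factor
    y = (coords[:, 0] + 0.5) * dy / factor
    pts = np.column_stack([x, y])
    if simplify_tol is None:
        simplify_tol = min(dx, dy) / factor / 4.0
    poly = Polygon(pts).buffer(0)
    if isinstance(poly, MultiPolygon):
        poly = max(poly.geoms, key=lambda g: g.area)
    if simplify_tol > 0:
        poly = poly.simplify(simplify_tol, preserve_topology=True)
    ext = np.asarray(poly.exterior.coords)[:-1]
    return Contour(surface=surface, frame=frame, slice_index=slice_index, points=ext)
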