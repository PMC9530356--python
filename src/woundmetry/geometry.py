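"""Exact polygon and projective-transform arithmetic.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` is the column axis (rightward), ``y`` the row axis (downward).
Bounding boxes are half-open ``[xmin, xmax) x [ymin, ymax)``.  Contours are
closed polygons (the last vertex connects implicitly back to the first) and
carry a frame tag — ``image`` for raw photograph coordinates, ``reference``
for the fiducial-marker reference plane in which physical sizes are defined.

A :class:`Homography` is a 3x3 projective transform with the bottom-right
entry normalized to exactly 1; it labels its source and target frames so
that applying a transform to a contour of the wrong frame is an error, not
a silent bug.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "GeometryError",
    "InvalidContourError",
    "DegenerateTransformError",
    "Contour",
    "BoundingBox",
    "Homography",
    "polygon_area",
    "polygon_perimeter",
    "apply_homography",
    "rotation_angle",
    "identity_homography",
    "translation_homography",
    "rotation_homography",
    "similarity_homography",
    "densify_contour",
    "smooth_closed_contour",
]


class Frame(str, enum.Enum):
    """Coordinate frame a contour or transform endpoint lives in."""

    IMAGE = "image"
    REFERENCE = "reference"


class GeometryError(ValueError):
    """Base class for geometric contract violations."""


class InvalidContourError(GeometryError):
    """Contour has fewer than 3 vertices, non-finite or duplicated points."""


class DegenerateTransformError(GeometryError):
    """Transform is singular or maps a point to infinity."""


@dataclass(frozen=True)
class Contour:
    """Closed polygon of 2-D points in a stated coordinate frame.

    Parameters
    ----------
    vertices
        ``(n, 2)`` float array of ``(x, y)`` points, ``n >= 3``.  The polygon
        is implicitly closed; do not repeat the first vertex at the end.
    frame
        Frame the coordinates are expressed in.
    """

    vertices: np.ndarray
    frame: Frame = Frame.IMAGE

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidContourError(f"expected (n, 2) vertices, got {v.shape}")
        if v.shape[0] < 3:
            raise InvalidContourError("a contour needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidContourError("contour vertices must be finite")
        nxt = np.roll(v, -1, axis=0)
        if np.any(np.all(v == nxt, axis=1)):
            raise InvalidContourError("duplicated consecutive vertices")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "frame", Frame(self.frame))

    def __len__(self) -> int:
        return int(self.vertices.shape[0])

    def to_record(self) -> dict:
        """GeoJSON-style serialization used inside report JSON."""
        return {
            "frame": self.frame.value,
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
        }

    @classmethod
    def from_record(cls, record: dict) -> "Contour":
        return cls(np.asarray(record["vertices"], dtype=float), Frame(record["frame"]))


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned pixel box ``[xmin, xmax) x [ymin, ymax)``."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        for name in ("xmin", "ymin", "xmax", "ymax"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if not (0 <= self.xmin < self.xmax and 0 <= self.ymin < self.ymax):
            raise GeometryError(
                f"invalid box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    def shift(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform with bottom-right entry fixed to 1.

    ``matrix`` maps homogeneous ``(x, y, 1)`` column vectors from
    ``source_frame`` to ``target_frame``.
    """

    matrix: np.ndarray
    source_frame: Frame = Frame.IMAGE
    target_frame: Frame = Frame.REFERENCE

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise DegenerateTransformError(f"expected 3x3 matrix, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise DegenerateTransformError("non-finite transform entries")
        if abs(m[2, 2]) < 1e-12:
            raise DegenerateTransformError("bottom-right entry is ~0; cannot normalize")
        m = m / m[2, 2]
        det = np.linalg.det(m)
        if abs(det) < 1e-12:
            raise DegenerateTransformError("transform matrix is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "source_frame", Frame(self.source_frame))
        object.__setattr__(self, "target_frame", Frame(self.target_frame))

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix), self.target_frame, self.source_frame)

    def compose(self, other: "Homography") -> "Homography":
        """Return ``self after other`` (apply ``other`` first)."""
        if other.target_frame != self.source_frame:
            raise GeometryError(
                f"cannot compose: {other.target_frame} -> {self.source_frame}"
            )
        return Homography(self.matrix @ other.matrix, other.source_frame, self.target_frame)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(n, 2)`` array of points; raises if any goes to infinity."""
        pts = np.asarray(points, dtype=float)
        homog = np.column_stack([pts, np.ones(len(pts))])
        mapped = homog @ self.matrix.T
        w = mapped[:, 2]
        if np.any(np.abs(w) <= 1e-12):
            raise DegenerateTransformError("point mapped to infinity (w ~ 0)")
        return mapped[:, :2] / w[:, None]


# ---------------------------------------------------------------------------
# polygon measures
# ---------------------------------------------------------------------------

def polygon_area(contour: Contour) -> float:
    """Unsigned polygon area by the shoelace formula.

    Orientation-independent; units are the square of the contour's
    coordinate unit (px^2 in image/reference frames, mm^2 after physical
    scaling).
    """
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(abs(np.sum(x * yn - xn * y)) / 2.0)


def signed_polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace sum / 2 (positive for CCW order in x-right/y-down)."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(np.sum(x * yn - xn * y) / 2.0)


def polygon_perimeter(contour: Contour) -> float:
    """Sum of Euclidean edge lengths, including the closing edge."""
    v = contour.vertices
    d = np.roll(v, -1, axis=0) - v
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


# ---------------------------------------------------------------------------
# projective transforms
# ---------------------------------------------------------------------------

def apply_homography(T: Homography, contour: Contour) -> Contour:
    """Transport a contour through ``T``; vertices are mapped homogeneously
    and divided by the third coordinate."""
    if contour.frame != T.source_frame:
        raise GeometryError(
            f"contour frame {contour.frame.value!r} != transform source "
            f"{T.source_frame.value!r}"
        )
    return Contour(T.transform_points(contour.vertices), T.target_frame)


def rotation_angle(T: Homography) -> float:
    """Rotation of the upper-left 2x2 block, in degrees in ``(-180, 180]``.

    The angle is that of the orthogonal factor of the polar decomposition
    ``M = U P`` of the affine 2x2 block — stable under anisotropic scale and
    shear, and equal to the plain rotation angle when the block is a scaled
    rotation.
    """
    m = T.matrix[:2, :2]
    det = np.linalg.det(m)
    if abs(det) < 1e-12:
        raise DegenerateTransformError("2x2 block is singular; no rotation defined")
    w, _, vt = np.linalg.svd(m)
    u = w @ vt
    deg = math.degrees(math.atan2(u[1, 0], u[0, 0]))
    if deg <= -180.0:
        deg += 360.0
    return deg


def identity_homography(source: Frame = Frame.IMAGE, target: Frame = Frame.REFERENCE) -> Homography:
    return Homography(np.eye(3), source, target)


def translation_homography(dx: float, dy: float, source: Frame = Frame.IMAGE,
                           target: Frame = Frame.REFERENCE) -> Homography:
    m = np.eye(3)
    m[0, 2], m[1, 2] = dx, dy
    return Homography(m, source, target)


def rotation_homography(deg: float, center: tuple[float, float] = (0.0, 0.0),
                        source: Frame = Frame.IMAGE,
                        target: Frame = Frame.REFERENCE) -> Homography:
    """Rotation by ``deg`` degrees about ``center`` (x-right, y-down axes)."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    cx, cy = center
    m = np.array(
        [
            [c, -s, cx - c * cx + s * cy],
            [s, c, cy - s * cx - c * cy],
            [0.0, 0.0, 1.0],
        ]
    )
    return Homography(m, source, target)


def similarity_homography(deg: float, scale: float, tx: float, ty: float,
                          source: Frame = Frame.IMAGE,
                          target: Frame = Frame.REFERENCE) -> Homography:
    c = scale * math.cos(math.radians(deg))
    s = scale * math.sin(math.radians(deg))
    m = np.array([[c, -s, tx], [s, c, ty], [0.0, 0.0, 1.0]])
    return Homography(m, source, target)


# ---------------------------------------------------------------------------
# contour resampling and smoothing
# ---------------------------------------------------------------------------

def densify_contour(contour: Contour, max_spacing: float = 0.5) -> np.ndarray:
    """Sample points along the closed polygon so consecutive samples are at
    most ``max_spacing`` apart.  Original vertices are retained.

    Returns a bare ``(n, 2)`` array (samples, not a simplified polygon).
    """
    if max_spacing <= 0:
        raise GeometryError("max_spacing must be positive")
    v = contour.vertices
    nxt = np.roll(v, -1, axis=0)
    out = []
    for a, b in zip(v, nxt):
        seg = b - a
        length = float(np.hypot(*seg))
        nseg = max(1, int(math.ceil(length / max_spacing)))
        t = np.arange(nseg) / nseg
        out.append(a + t[:, None] * seg)
    return np.concatenate(out, axis=0)


def smooth_closed_contour(contour: Contour, sigma: float = 2.0,
                          spacing: float = 0.5) -> Contour:
    """Low-pass a closed contour: resample to uniform ``spacing`` then apply
    a circular Gaussian filter of width ``sigma`` (same units as the
    coordinates) to x and y independently.

    Used to recover smooth-boundary perimeters from pixel-aligned (staircase)
    polygons, whose raw edge length overestimates a smooth boundary's length
    by up to 4/pi.
    """
    from scipy.ndimage import gaussian_filter1d

    pts = densify_contour(contour, spacing)
    if len(pts) < 8:
        return contour
    sx = gaussian_filter1d(pts[:, 0], sigma / spacing, mode="wrap")
    sy = gaussian_filter1d(pts[:, 1], sigma / spacing, mode="wrap")
    sm = np.column_stack([sx, sy])
    # drop any consecutive duplicates the filter may create
    keep = np.any(sm != np.roll(sm, 1, axis=0), axis=1)
    sm = sm[keep]
    if sm.shape[0] < 3:
        return contour
    return Contour(sm, contour.frame)
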