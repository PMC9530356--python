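"""Wound characteristics computation: orchestration of the full pipeline.

Per image: each detected wound box is histogram-adjusted, segmented with
box-initialized GrabCut, and reduced to its largest boundary contour; the
fiducial marker is registered once to obtain the image-to-reference
transform; if the transform rotates by more than the quality-gate threshold
the image is not analyzed further.  Otherwise every wound contour is
transported into the reference frame and scaled by the reference's
mm-per-pixel to yield physical area (mm^2) and perimeter (mm).

Also houses the contour-accuracy metric used for validation: the percentile
Hausdorff distance (the 90th percentile variant is robust to small spurs a
segmenter may leave; percentile 100 reproduces the classic Hausdorff
distance).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import exposure

from . import __version__
from .geometry import (
    BoundingBox,
    Contour,
    Frame,
    InvalidContourError,
    apply_homography,
    densify_contour,
    polygon_area,
    polygon_perimeter,
    smooth_closed_contour,
)
from .grabcut import GrabcutParams, extract_contours, grabcut_segment
from .registration import (
    MarkerReference,
    RegistrationError,
    RegistrationResult,
    register_marker,
)

__all__ = [
    "AnnotationError",
    "UnanalyzableImageError",
    "CLASS_ID_MAP",
    "DetectionRecord",
    "WoundMeasurement",
    "ImageMeasurement",
    "adjust_histogram",
    "measure_wounds",
    "percentile_hausdorff",
    "average_hausdorff",
    "wound_report",
    "save_overlay",
]

#: wound class-id map used in the detection annotations
CLASS_ID_MAP = {"blocked_vessel": 0, "suture": 1, "ulceration": 2, "marker": 3}
_ID_CLASS_MAP = {v: k for k, v in CLASS_ID_MAP.items()}


class AnnotationError(ValueError):
    pass


class UnanalyzableImageError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectionRecord:
    """One detector output: a box with a class label and optional score."""

    box: BoundingBox
    class_label: str
    score: float | None = None

    def __post_init__(self) -> None:
        label = self.class_label
        if isinstance(label, (int, np.integer)):
            try:
                label = _ID_CLASS_MAP[int(label)]
            except KeyError:
                raise AnnotationError(f"unknown class id {label}") from None
        if label not in CLASS_ID_MAP:
            raise AnnotationError(f"unknown class {label!r}")
        object.__setattr__(self, "class_label", label)
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise AnnotationError("score must lie in [0, 1]")

    @property
    def is_marker(self) -> bool:
        return self.class_label == "marker"

    @property
    def class_id(self) -> int:
        return CLASS_ID_MAP[self.class_label]


@dataclass
class WoundMeasurement:
    """One wound's physical measurement in the reference frame."""

    class_label: str
    contour_ref: Contour
    area_mm2: float
    perimeter_mm: float
    segmentation_warning: bool = False


@dataclass
class ImageMeasurement:
    """Everything the pipeline derived from one image."""

    measurements: list[WoundMeasurement]
    registration: RegistrationResult | None
    unanalyzable: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# histogram adjustment
# ---------------------------------------------------------------------------

def adjust_histogram(subimage: np.ndarray) -> np.ndarray:
    """Per-channel histogram equalization to the full 8-bit range.

    Monotone per channel (pixel ordering is preserved); idempotent up to
    quantization.
    """
    img = np.asarray(subimage)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB sub-image")
    out = np.empty_like(img, dtype=np.uint8)
    for c in range(3):
        eq = exposure.equalize_hist(img[:, :, c])
        out[:, :, c] = np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# end-to-end measurement
# ---------------------------------------------------------------------------

def measure_wounds(image: np.ndarray, detections: list[DetectionRecord],
                   reference: MarkerReference,
                   params: GrabcutParams | None = None,
                   margin: int = 8, min_area: float = 16.0,
                   contour_smooth_sigma: float = 1.5,
                   threshold_deg: float = 15.0,
                   equalize: bool = True) -> ImageMeasurement:
    """Measure every detected wound of one image in physical units.

    Parameters
    ----------
    image
        Full RGB photograph.
    detections
        Exactly one marker record plus at least one wound record.
    reference
        Reference marker with its physical scale.
    params
        GrabCut parameters (defaults used when omitted).
    margin
        Pixels of context added around each wound box before segmentation
        (the box itself still clamps the background).
    min_area
        Smallest connected component (px^2) kept as a wound candidate.
    contour_smooth_sigma
        Width (px) of the boundary low-pass applied to the raster contour
        before transport; pixel-staircase boundaries otherwise overestimate
        smooth perimeters by up to 4/pi.
    threshold_deg
        Rotation quality gate; images rotated more are not analyzed.
    equalize
        Apply the per-box histogram adjustment before segmentation.
    """
    markers = [d for d in detections if d.is_marker]
    wounds = [d for d in detections if not d.is_marker]
    if len(markers) != 1:
        raise AnnotationError(f"need exactly one marker record, got {len(markers)}")
    if not wounds:
        raise AnnotationError("need at least one wound record")
    if params is None:
        params = GrabcutParams()

    try:
        registration = register_marker(image, markers[0].box, reference,
                                       threshold_deg=threshold_deg,
                                       seed=params.seed)
    except RegistrationError as exc:
        return ImageMeasurement([], None, True, reason=f"registration failed: {exc}")

    if not registration.qc_pass:
        return ImageMeasurement(
            [], registration, True,
            reason=f"rotation {registration.rotation_deg:.1f} deg exceeds "
                   f"{threshold_deg:.0f} deg gate",
        )

    h, w = image.shape[:2]
    results: list[WoundMeasurement] = []
    for det in wounds:
        box = det.box
        x0 = max(0, box.xmin - margin)
        y0 = max(0, box.ymin - margin)
        x1 = min(w, box.xmax + margin)
        y1 = min(h, box.ymax + margin)
        crop = image[y0:y1, x0:x1]
        if equalize:
            crop = adjust_histogram(crop)
        local_box = BoundingBox(box.xmin - x0, box.ymin - y0,
                                box.xmax - x0, box.ymax - y0)
        seg = grabcut_segment(crop, local_box, params)
        contours = extract_contours(seg.mask, min_area=min_area)
        if not contours:
            results.append(WoundMeasurement(det.class_label, None, 0.0, 0.0,
                                            segmentation_warning=True))
            continue
        largest = max(contours, key=polygon_area)
        smoothed = smooth_closed_contour(largest, sigma=contour_smooth_sigma)
        global_contour = Contour(smoothed.vertices + [x0, y0], Frame.IMAGE)
        contour_ref = apply_homography(registration.transform, global_contour)
        mm = reference.mm_per_pixel
        results.append(
            WoundMeasurement(
                class_label=det.class_label,
                contour_ref=contour_ref,
                area_mm2=polygon_area(contour_ref) * mm**2,
                perimeter_mm=polygon_perimeter(contour_ref) * mm,
                segmentation_warning=seg.empty_foreground,
            )
        )
    return ImageMeasurement(results, registration, False)


# ---------------------------------------------------------------------------
# contour accuracy metrics
# ---------------------------------------------------------------------------

def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return d


def percentile_hausdorff(predicted: Contour, truth: Contour,
                         percentile: float = 90.0,
                         spacing: float = 0.5) -> float:
    """Symmetric percentile Hausdorff distance between two closed contours.

    Both contours are densified to at most ``spacing``-unit edge sampling so
    the statistic does not depend on vertex count; the result is the larger
    of the two directed p-th percentiles of point-to-set distances.
    ``percentile=100`` reproduces the classic Hausdorff distance.
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    if predicted is None or truth is None:
        raise InvalidContourError("degenerate contour")
    pa = densify_contour(predicted, spacing)
    pb = densify_contour(truth, spacing)
    dab = np.percentile(_directed_distances(pa, pb), percentile)
    dba = np.percentile(_directed_distances(pb, pa), percentile)
    return float(max(dab, dba))


def average_hausdorff(predicted: Contour, truth: Contour,
                      spacing: float = 0.5) -> float:
    """Average (symmetrized) Hausdorff distance: mean of the two directed
    mean point-to-set distances."""
    pa = densify_contour(predicted, spacing)
    pb = densify_contour(truth, spacing)
    return float((_directed_distances(pa, pb).mean()
                  + _directed_distances(pb, pa).mean()) / 2.0)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def wound_report(result: ImageMeasurement, params: GrabcutParams | None = None,
                 provenance: dict | None = None) -> dict:
    """Deterministic JSON-serializable report for one image."""
    params = params or GrabcutParams()
    param_dict = {
        "K": params.K, "gamma": params.gamma, "max_iters": params.max_iters,
        "energy_rel_tol": params.energy_rel_tol, "cov_reg": params.cov_reg,
        "seed": params.seed,
    }
    report = {
        "tool": "woundmetry",
        "version": __version__,
        "params": param_dict,
        "params_hash": _params_hash(param_dict),
        "provenance": provenance or {},
        "unanalyzable": result.unanalyzable,
        "reason": result.reason,
        "registration": None,
        "wounds": [],
    }
    if result.registration is not None:
        reg = result.registration
        report["registration"] = {
            "transform": [[float(v) for v in row] for row in reg.transform.matrix],
            "rotation_deg": float(reg.rotation_deg),
            "qc_pass": bool(reg.qc_pass),
            "residual_rms_px": float(reg.residual_rms),
            "n_inliers": int(reg.n_inliers),
        }
    for m in result.measurements:
        entry = {
            "class": m.class_label,
            "class_id": CLASS_ID_MAP[m.class_label],
            "area_mm2": float(m.area_mm2),
            "perimeter_mm": float(m.perimeter_mm),
            "segmentation_warning": bool(m.segmentation_warning),
            "contour": m.contour_ref.to_record() if m.contour_ref is not None else None,
        }
        report["wounds"].append(entry)
    return report


def save_overlay(image: np.ndarray, result: ImageMeasurement, path,
                 registration_inverse: bool = True) -> None:
    """Write a PNG with each measured wound contour stroked in red."""
    from PIL import Image, ImageDraw

    im = Image.fromarray(np.asarray(image).astype(np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(im)
    for m in result.measurements:
        if m.contour_ref is None:
            continue
        contour = m.contour_ref
        if registration_inverse and result.registration is not None:
            contour = apply_homography(result.registration.transform.inverse(),
                                       contour)
        pts = [tuple(p) for p in contour.vertices]
        draw.line(pts + [pts[0]], fill=(255, 0, 0), width=2)
    im.save(path)
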