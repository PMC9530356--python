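"""Ground-truthed synthetic scene generator.

Emulates the structure of clinical wound photographs — a skin-toned
background, one to a few wound regions of three classes (blocked blood
vessel, suture, ulceration) rendered as color-contrasting perturbed
ellipses, and one square high-texture fiducial marker pasted under a known
projective transform — so every pipeline stage can be exercised against
exact ground truth (masks, contours, boxes, the true image-to-reference
homography, and physical areas/perimeters).  Not a photorealistic
simulator: real tissue texture, specular highlights, shadows and camera
blur are deliberately absent.

All randomness flows from the scene seed; generation is byte-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.transform import ProjectiveTransform, warp

from .geometry import (
    BoundingBox,
    Contour,
    Frame,
    Homography,
    apply_homography,
    polygon_area,
    polygon_perimeter,
)

__all__ = [
    "WOUND_CLASSES",
    "InvalidSpecError",
    "WoundSpec",
    "MarkerSpec",
    "SceneSpec",
    "SceneGroundTruth",
    "make_reference_marker",
    "generate_scene",
    "default_scene_spec",
    "perturb_scene",
    "generate_fixture_dataset",
    "PAPER_CLASS_COUNTS",
]

WOUND_CLASSES = ("blocked_vessel", "suture", "ulceration")

#: original per-class image counts of the study dataset, used as fixture defaults
PAPER_CLASS_COUNTS = {"blocked_vessel": 318, "suture": 64, "ulceration": 345}

_CLASS_COLORS = {
    "blocked_vessel": (62.0, 38.0, 72.0),   # dark purple, occluded tissue
    "suture": (192.0, 118.0, 128.0),        # pink, elongated
    "ulceration": (165.0, 52.0, 42.0),      # raw red
}

_BACKGROUND_COLOR = (205.0, 170.0, 150.0)   # skin tone


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class WoundSpec:
    """One wound region: a perturbed ellipse with its own color statistics."""

    class_label: str
    center: tuple[float, float]
    axes: tuple[float, float]
    angle_deg: float = 0.0
    color: tuple[float, float, float] = (165.0, 52.0, 42.0)
    color_sd: float = 0.0
    irregularity: float = 0.08      # radial sinusoid amplitude, fraction of radius
    lobes: int = 5
    phase: float = 0.0


@dataclass(frozen=True)
class MarkerSpec:
    """Placement of the reference marker in the scene.

    ``rotation_deg`` is the rotation of the recovered image->reference
    transform (the quantity the quality gate inspects); ``perspective``
    holds the two projective entries of the placement.
    """

    center: tuple[float, float] = (250.0, 250.0)
    scale: float = 0.7
    rotation_deg: float = 0.0
    perspective: tuple[float, float] = (0.0, 0.0)
    physical_side_mm: float = 30.0


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int] = (320, 320)
    wounds: tuple[WoundSpec, ...] = ()
    marker: MarkerSpec = field(default_factory=MarkerSpec)
    background_color: tuple[float, float, float] = _BACKGROUND_COLOR
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class SceneGroundTruth:
    masks: list[np.ndarray]
    contours: list[Contour]            # image frame
    contours_ref: list[Contour]        # reference frame
    class_labels: list[str]
    boxes: list[BoundingBox]
    marker_box: BoundingBox
    transform: Homography              # image -> reference
    mm_per_pixel: float                # of the reference plane
    areas_mm2: list[float]
    perimeters_mm: list[float]
    spec: SceneSpec


# ---------------------------------------------------------------------------
# reference marker
# ---------------------------------------------------------------------------

def make_reference_marker(size: int = 128, seed: int = 7) -> np.ndarray:
    """Square reference marker: smooth aperiodic two-scale random texture
    inside a dark border.

    Aperiodic (seeded-random) rather than a checkerboard so descriptor
    matching survives the ratio test — repeated identical corners would make
    every nearest/second-nearest distance ratio ~1.  Smooth rather than
    blocky because hard block corners quantize keypoint localization to the
    pixel grid, which under fractional image scale turns into spatially
    correlated errors that bias the fitted transform.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    coarse = gaussian_filter(rng.normal(size=(size, size)), 3.0)
    fine = gaussian_filter(rng.normal(size=(size, size)), 1.2)
    tex = coarse / coarse.std() * 0.6 + fine / fine.std() * 0.4
    tex = (tex - tex.min()) / (tex.max() - tex.min()) * 255.0
    tex[:4, :] = 0
    tex[-4:, :] = 0
    tex[:, :4] = 0
    tex[:, -4:] = 0
    return np.repeat(tex[:, :, None], 3, axis=2).astype(np.uint8)


# ---------------------------------------------------------------------------
# marker placement homography
# ---------------------------------------------------------------------------

def _placement_matrix(marker: MarkerSpec, ref_size: int) -> np.ndarray:
    """Reference->image placement matrix. Built so the image->reference
    inverse has rotation angle exactly ``marker.rotation_deg``."""
    cx, cy = marker.center
    half = ref_size / 2.0
    th = math.radians(-marker.rotation_deg)
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    scale = np.diag([marker.scale, marker.scale, 1.0])
    persp = np.eye(3)
    persp[2, 0], persp[2, 1] = marker.perspective
    t_in = np.array([[1, 0, -half], [0, 1, -half], [0, 0, 1.0]])
    t_out = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    return t_out @ rot @ scale @ persp @ t_in


def _marker_truth(marker: MarkerSpec, ref_size: int) -> tuple[np.ndarray, Homography, BoundingBox]:
    place = _placement_matrix(marker, ref_size)
    truth_T = Homography(np.linalg.inv(place), Frame.IMAGE, Frame.REFERENCE)
    corners = np.array(
        [[0, 0], [ref_size, 0], [ref_size, ref_size], [0, ref_size]], dtype=float
    )
    homog = np.column_stack([corners, np.ones(4)])
    mapped = homog @ place.T
    mapped = mapped[:, :2] / mapped[:, 2:3]
    xmin, ymin = np.floor(mapped.min(axis=0)) - 1
    xmax, ymax = np.ceil(mapped.max(axis=0)) + 1
    box = BoundingBox(max(0, int(xmin)), max(0, int(ymin)), int(xmax), int(ymax))
    return place, truth_T, box


# ---------------------------------------------------------------------------
# wound shapes
# ---------------------------------------------------------------------------

def _wound_polygon(w: WoundSpec, n: int = 180) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    radial = 1.0 + w.irregularity * np.sin(w.lobes * t + w.phase)
    ex = w.axes[0] * radial * np.cos(t)
    ey = w.axes[1] * radial * np.sin(t)
    ang = math.radians(w.angle_deg)
    c, s = math.cos(ang), math.sin(ang)
    x = w.center[0] + c * ex - s * ey
    y = w.center[1] + s * ex + c * ey
    return np.column_stack([x, y])


def _boxes_overlap(a: BoundingBox, b: BoundingBox, margin: int = 0) -> bool:
    return not (
        a.xmax + margin <= b.xmin
        or b.xmax + margin <= a.xmin
        or a.ymax + margin <= b.ymin
        or b.ymax + margin <= a.ymin
    )


# ---------------------------------------------------------------------------
# scene synthesis
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec,
                   reference: np.ndarray | None = None) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a scene and its exact ground truth.

    Raises :class:`InvalidSpecError` if wound/marker regions overlap.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    if reference is None:
        reference = make_reference_marker()
    ref_size = reference.shape[0]

    img = np.empty((h, w, 3), dtype=float)
    img[...] = spec.background_color
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    place, truth_T, marker_box = _marker_truth(spec.marker, ref_size)

    masks, contours, contours_ref, boxes, labels = [], [], [], [], []
    areas, perims = [], []
    mm_per_pixel = spec.marker.physical_side_mm / ref_size

    for wound in spec.wounds:
        poly = _wound_polygon(wound)
        contour = Contour(poly, Frame.IMAGE)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        xmin = max(0, int(np.floor(poly[:, 0].min())) - 1)
        ymin = max(0, int(np.floor(poly[:, 1].min())) - 1)
        xmax = min(w, int(np.ceil(poly[:, 0].max())) + 1)
        ymax = min(h, int(np.ceil(poly[:, 1].max())) + 1)
        box = BoundingBox(xmin, ymin, xmax, ymax)
        for other in boxes + [marker_box]:
            if _boxes_overlap(box, other):
                raise InvalidSpecError("wound region overlaps another region")

        img[mask] = wound.color
        if wound.color_sd > 0 or spec.noise_sd > 0:
            sd = max(wound.color_sd, spec.noise_sd)
            img[mask] += rng.normal(0.0, sd, (int(mask.sum()), 3))

        cref = apply_homography(truth_T, contour)
        masks.append(mask)
        contours.append(contour)
        contours_ref.append(cref)
        boxes.append(box)
        labels.append(wound.class_label)
        areas.append(polygon_area(cref) * mm_per_pixel**2)
        perims.append(polygon_perimeter(cref) * mm_per_pixel)

    # paste the marker: warp needs the output->input (image->reference) map
    tform = ProjectiveTransform(matrix=truth_T.matrix)
    warped = warp(reference.astype(float), tform, output_shape=(h, w),
                  order=1, cval=0.0)
    coverage = warp(np.ones(reference.shape[:2]), tform, output_shape=(h, w),
                    order=1, cval=0.0)
    marker_mask = coverage > 0.5
    img[marker_mask] = warped[marker_mask]

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = SceneGroundTruth(
        masks=masks,
        contours=contours,
        contours_ref=contours_ref,
        class_labels=labels,
        boxes=boxes,
        marker_box=marker_box,
        transform=truth_T,
        mm_per_pixel=mm_per_pixel,
        areas_mm2=areas,
        perimeters_mm=perims,
        spec=spec,
    )
    return img, truth


def default_scene_spec(class_label: str = "ulceration", seed: int = 0,
                       rotation_deg: float = 5.0, noise_sd: float = 2.0,
                       image_size: tuple[int, int] = (320, 320)) -> SceneSpec:
    """A study-like single-wound scene: one wound of the given class in the
    upper-left region, the marker in the lower-right corner."""
    if class_label not in WOUND_CLASSES:
        raise InvalidSpecError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    cx = float(rng.uniform(65, 135))
    cy = float(rng.uniform(65, 135))
    if class_label == "suture":
        axes = (float(rng.uniform(30, 40)), float(rng.uniform(9, 13)))
    else:
        axes = (float(rng.uniform(24, 36)), float(rng.uniform(17, 27)))
    wound = WoundSpec(
        class_label=class_label,
        center=(cx, cy),
        axes=axes,
        angle_deg=float(rng.uniform(0, 180)),
        color=_CLASS_COLORS[class_label],
        color_sd=noise_sd,
        irregularity=float(rng.uniform(0.04, 0.10)),
        lobes=int(rng.integers(3, 7)),
        phase=float(rng.uniform(0, 2 * np.pi)),
    )
    marker = MarkerSpec(rotation_deg=rotation_deg)
    return SceneSpec(image_size=image_size, wounds=(wound,), marker=marker,
                     noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))


def perturb_scene(image: np.ndarray, truth: SceneGroundTruth,
                  rotation_deg: float = 0.0,
                  noise_sd: float | None = None) -> tuple[np.ndarray, SceneGroundTruth]:
    """Re-render a scene with the marker homography composed with an extra
    in-plane rotation about the marker center; ground truth is updated
    consistently (the recovered transform's rotation grows by exactly
    ``rotation_deg``)."""
    spec = truth.spec
    marker = replace(spec.marker, rotation_deg=spec.marker.rotation_deg + rotation_deg)
    new_spec = replace(
        spec,
        marker=marker,
        noise_sd=spec.noise_sd if noise_sd is None else noise_sd,
    )
    return generate_scene(new_spec)


# ---------------------------------------------------------------------------
# fixture dataset emission
# ---------------------------------------------------------------------------

def generate_fixture_dataset(class_counts: dict[str, int] | None = None,
                             out_dir=None, seed: int = 0,
                             image_size: tuple[int, int] = (320, 320),
                             render: bool = True) -> list[dict]:
    """Emit a ground-truthed image/annotation fixture tree.

    One scene per requested image, each holding one wound of the class plus
    the marker.  Returns the annotation records
    (``filename, width, height, class, xmin, ymin, xmax, ymax`` with the
    marker as an extra object per image); with ``render=True`` and an
    ``out_dir``, PNG images and Pascal-VOC XML files are written alongside.
    With ``render=False`` only the geometry is computed, which makes
    printed-scale bookkeeping runs cheap.
    """
    from .dataset import write_voc_xml  # local import; dataset also imports us

    if class_counts is None:
        class_counts = dict(PAPER_CLASS_COUNTS)
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    h, w = image_size
    for label in sorted(class_counts):
        if class_counts[label] <= 0:
            raise InvalidSpecError("class counts must be positive")
        for i in range(class_counts[label]):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            spec = default_scene_spec(label, seed=scene_seed,
                                      rotation_deg=float(rng.uniform(-10, 10)),
                                      image_size=image_size)
            fname = f"{label}_{i:04d}.png"
            if render:
                image, truth = generate_scene(spec)
            else:
                # geometry only: wound polygon and marker corners, no pixels
                poly = _wound_polygon(spec.wounds[0])
                xmin = max(0, int(np.floor(poly[:, 0].min())) - 1)
                ymin = max(0, int(np.floor(poly[:, 1].min())) - 1)
                xmax = min(w, int(np.ceil(poly[:, 0].max())) + 1)
                ymax = min(h, int(np.ceil(poly[:, 1].max())) + 1)
                ref = make_reference_marker()
                _, _, mbox = _marker_truth(spec.marker, ref.shape[0])
                truth = None
                wound_box = BoundingBox(xmin, ymin, xmax, ymax)
            if truth is not None:
                wound_box = truth.boxes[0]
                mbox = truth.marker_box
            image_records = [
                {"filename": fname, "width": w, "height": h, "class": label,
                 "xmin": wound_box.xmin, "ymin": wound_box.ymin,
                 "xmax": wound_box.xmax, "ymax": wound_box.ymax},
                {"filename": fname, "width": w, "height": h, "class": "marker",
                 "xmin": mbox.xmin, "ymin": mbox.ymin,
                 "xmax": min(mbox.xmax, w), "ymax": min(mbox.ymax, h)},
            ]
            records.extend(image_records)
            if out_dir is not None:
                from pathlib import Path

                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                if render:
                    from PIL import Image

                    Image.fromarray(image).save(out / fname)
                write_voc_xml(image_records, out / (fname[:-4] + ".xml"))
    return records
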