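"""Fiducial-marker registration and the rotation quality gate.

The in-image marker crop is matched to the reference marker image through
scale-invariant interest points (ORB keypoints + binary descriptors, ratio
test, RANSAC consensus on a projective model).  The surviving
correspondences ``z_Mi = (x_i, y_i) -> z_RMi = (x_Ri, y_Ri)`` feed a direct
linear transform: the ``2k x 8`` system

    [ x  y  1  0  0  0  -x*xR  -y*xR ] [A1..A8]^T = xR
    [ 0  0  0  x  y  1  -x*yR  -y*yR ]            = yR

is solved in the least-squares sense (exactly when k = 4) and the transform
matrix assembled with its bottom-right entry fixed to 1.  Images whose
recovered transform rotates by more than 15 degrees are flagged
unanalyzable — oblique shots make the planar marker a poor proxy for the
wound plane.

The detector backend is deliberately pluggable (any detector returning
matched point pairs will do); the contract is correspondence quality, not a
particular descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .geometry import (
    BoundingBox,
    DegenerateTransformError,
    Frame,
    Homography,
    rotation_angle,
    translation_homography,
)

__all__ = [
    "RegistrationError",
    "InsufficientFeaturesError",
    "DegenerateConfigurationError",
    "CorrespondenceSet",
    "MarkerReference",
    "RegistrationResult",
    "match_marker_features",
    "solve_projective_transform",
    "refine_transform_photometric",
    "qc_rotation_gate",
    "register_marker",
    "ROTATION_GATE_DEG",
]

#: images rotated beyond this are not analyzed further
ROTATION_GATE_DEG = 15.0


class RegistrationError(RuntimeError):
    pass


class InsufficientFeaturesError(RegistrationError):
    pass


class DegenerateConfigurationError(RegistrationError):
    pass


@dataclass(frozen=True)
class CorrespondenceSet:
    """Matched point pairs, image frame -> reference frame."""

    source: np.ndarray  # (k, 2) image-frame points
    target: np.ndarray  # (k, 2) reference-frame points

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float)
        dst = np.asarray(self.target, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise RegistrationError("source/target must both be (k, 2)")
        if src.shape[0] < 4:
            raise RegistrationError("need at least 4 correspondences")
        if len(np.unique(src, axis=0)) != src.shape[0]:
            raise RegistrationError("duplicated source points")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", dst)

    @property
    def k(self) -> int:
        return int(self.source.shape[0])


@dataclass(frozen=True)
class MarkerReference:
    """Reference marker image with its physical scale.

    ``mm_per_pixel`` anchors every physical unit the pipeline reports.
    """

    image: np.ndarray
    mm_per_pixel: float
    physical_side_mm: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")

    @classmethod
    def from_physical_side(cls, image: np.ndarray, physical_side_mm: float) -> "MarkerReference":
        side_px = image.shape[1]
        return cls(image=image, mm_per_pixel=physical_side_mm / side_px,
                   physical_side_mm=physical_side_mm)


@dataclass
class RegistrationResult:
    transform: Homography          # full image frame -> reference frame
    rotation_deg: float
    qc_pass: bool
    residual_rms: float            # reference-frame pixels
    n_inliers: int


# ---------------------------------------------------------------------------
# feature matching
# ---------------------------------------------------------------------------

def _gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        return rgb2gray(image)
    return image.astype(float) / 255.0 if image.dtype == np.uint8 else image


def match_marker_features(marker_subimage: np.ndarray, reference: MarkerReference,
                          min_pairs: int = 8, ratio: float = 0.75,
                          ransac_threshold: float = 3.0,
                          seed: int = 0) -> CorrespondenceSet:
    """Detect, describe, match and prune interest points between the marker
    crop and the reference marker.

    Raises :class:`InsufficientFeaturesError` when fewer than ``min_pairs``
    inlier pairs survive; such an image is unanalyzable.
    """
    img_g = _gray(marker_subimage)
    ref_g = _gray(reference.image)
    if img_g.size == 0 or ref_g.size == 0:
        raise InsufficientFeaturesError("empty image")

    def _detect(g):
        orb = ORB(n_keypoints=800, fast_threshold=0.02)
        try:
            orb.detect_and_extract(g)
        except (RuntimeError, ValueError) as exc:
            raise InsufficientFeaturesError(f"no interest points: {exc}") from exc
        return orb.keypoints, orb.descriptors

    kp_img, des_img = _detect(img_g)
    kp_ref, des_ref = _detect(ref_g)
    if len(kp_img) < min_pairs or len(kp_ref) < min_pairs:
        raise InsufficientFeaturesError("too few interest points")

    matches = match_descriptors(des_img, des_ref, cross_check=True, max_ratio=ratio)
    if matches.shape[0] < max(min_pairs, 4):
        raise InsufficientFeaturesError(f"only {matches.shape[0]} raw matches")

    # keypoints are (row, col); switch to (x, y)
    src = kp_img[matches[:, 0]][:, ::-1]
    dst = kp_ref[matches[:, 1]][:, ::-1]
    try:
        model, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=ransac_threshold,
            max_trials=1000,
            rng=seed,
        )
    except ValueError as exc:
        raise InsufficientFeaturesError(f"consensus failed: {exc}") from exc
    if model is None or inliers is None or int(inliers.sum()) < min_pairs:
        n = 0 if inliers is None else int(inliers.sum())
        raise InsufficientFeaturesError(f"only {n} consensus inliers")

    src_in, dst_in = src[inliers], dst[inliers]
    # de-duplicate source points (two descriptors can share a keypoint)
    _, keep = np.unique(src_in, axis=0, return_index=True)
    keep = np.sort(keep)
    if keep.size < min_pairs:
        raise InsufficientFeaturesError("too few unique inlier sources")
    return CorrespondenceSet(src_in[keep], dst_in[keep])


# ---------------------------------------------------------------------------
# direct linear transform
# ---------------------------------------------------------------------------

def solve_projective_transform(correspondences: CorrespondenceSet) -> tuple[Homography, float]:
    """Solve the 2k x 8 DLT system for the image->reference homography.

    Returns the transform (bottom-right entry 1) and the RMS reprojection
    residual in reference pixels.  Exact for k = 4 non-degenerate points;
    least squares for k > 4.
    """
    src, dst = correspondences.source, correspondences.target
    k = correspondences.k
    x, y = src[:, 0], src[:, 1]
    xr, yr = dst[:, 0], dst[:, 1]

    design = np.zeros((2 * k, 8))
    design[0::2, 0] = x
    design[0::2, 1] = y
    design[0::2, 2] = 1.0
    design[0::2, 6] = -x * xr
    design[0::2, 7] = -y * xr
    design[1::2, 3] = x
    design[1::2, 4] = y
    design[1::2, 5] = 1.0
    design[1::2, 6] = -x * yr
    design[1::2, 7] = -y * yr
    rhs = np.empty(2 * k)
    rhs[0::2] = xr
    rhs[1::2] = yr

    a, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 8:
        raise DegenerateConfigurationError(
            "rank-deficient DLT system (collinear or duplicated points)"
        )
    matrix = np.append(a, 1.0).reshape(3, 3)
    try:
        T = Homography(matrix, Frame.IMAGE, Frame.REFERENCE)
        projected = T.transform_points(src)
    except DegenerateTransformError as exc:
        raise DegenerateConfigurationError(str(exc)) from exc
    residual_rms = float(np.sqrt(np.mean(np.sum((projected - dst) ** 2, axis=1))))
    return T, residual_rms


def refine_transform_photometric(marker_subimage: np.ndarray,
                                 reference: MarkerReference,
                                 T0: Homography, max_nfev: int = 200) -> Homography:
    """Polish a crop-local transform by direct intensity alignment.

    Gauss-Newton (Levenberg-Marquardt) on the 8 free transform entries,
    minimizing the squared grayscale difference between the marker crop and
    the reference sampled at the transformed coordinates.  Pixels mapping
    outside the reference are excluded.  Keypoint localization noise limits
    a correspondence-only fit to a few tenths of a degree of rotation;
    photometric refinement works at the resolution of the intensity surface
    instead.
    """
    from scipy.ndimage import map_coordinates
    from scipy.optimize import least_squares

    crop_g = _gray(marker_subimage) * 255.0
    ref_g = _gray(reference.image) * 255.0
    h, w = crop_g.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.ones(h * w)])
    intensities = crop_g.ravel()

    def residuals(p: np.ndarray) -> np.ndarray:
        m = pts @ np.append(p, 1.0).reshape(3, 3).T
        u = m[:, 0] / m[:, 2]
        v = m[:, 1] / m[:, 2]
        sampled = map_coordinates(ref_g, [v, u], order=1, mode="constant",
                                  cval=np.nan)
        r = intensities - sampled
        r[~np.isfinite(r)] = 0.0
        return r

    sol = least_squares(residuals, T0.matrix.ravel()[:8], method="lm",
                        x_scale="jac", max_nfev=max_nfev)
    return Homography(np.append(sol.x, 1.0).reshape(3, 3),
                      T0.source_frame, T0.target_frame)


def qc_rotation_gate(T: Homography, threshold_deg: float = ROTATION_GATE_DEG) -> bool:
    """True iff the transform's rotation magnitude is within the gate
    (boundary inclusive: only strictly larger angles are rejected)."""
    return abs(rotation_angle(T)) <= threshold_deg


# ---------------------------------------------------------------------------
# end-to-end marker registration
# ---------------------------------------------------------------------------

def register_marker(image: np.ndarray, marker_box: BoundingBox,
                    reference: MarkerReference, min_pairs: int = 8,
                    threshold_deg: float = ROTATION_GATE_DEG,
                    refine: bool = True, seed: int = 0) -> RegistrationResult:
    """Crop the marker, match features, solve the transform, apply the gate.

    With ``refine=True`` (default) the correspondence-based solution is
    polished photometrically.  The returned transform maps *full-image*
    coordinates (not crop-local ones) to reference coordinates: the crop
    offset is pre-composed.
    """
    h, w = image.shape[:2]
    crop = image[marker_box.ymin:min(marker_box.ymax, h),
                 marker_box.xmin:min(marker_box.xmax, w)]
    corr = match_marker_features(crop, reference, min_pairs=min_pairs, seed=seed)
    T_local, residual = solve_projective_transform(corr)
    if refine:
        T_local = refine_transform_photometric(crop, reference, T_local)
        projected = T_local.transform_points(corr.source)
        residual = float(np.sqrt(np.mean(np.sum((projected - corr.target) ** 2,
                                                axis=1))))
    offset = translation_homography(-marker_box.xmin, -marker_box.ymin,
                                    Frame.IMAGE, Frame.IMAGE)
    T_global = T_local.compose(offset)
    rot = rotation_angle(T_global)
    return RegistrationResult(
        transform=T_global,
        rotation_deg=rot,
        qc_pass=abs(rot) <= threshold_deg,
        residual_rms=residual,
        n_inliers=corr.k,
    )
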