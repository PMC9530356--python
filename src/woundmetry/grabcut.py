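"""Box-initialized GrabCut segmentation, implemented from scratch.

GrabCut alternates three block-coordinate steps on a trimap initialized from
a rectangle: (1) assign every pixel to the most probable component of its
current side's color Gaussian mixture model, (2) re-estimate both GMMs from
the assignments, (3) solve a global min-cut on a pixel graph whose terminal
links carry the GMM data costs and whose neighbor links are
contrast-sensitive.  Each step cannot increase the total energy

    E = sum_n min_k ( -log pi_k - log N(z_n; mu_k, Sigma_k) )
        + gamma * sum_{(m,n) in C, alpha_m != alpha_n}
              dis(m,n)^-1 * exp(-beta * ||z_m - z_n||^2)

so the per-iteration energy trace is non-increasing (up to the integer
rounding used by the max-flow solver).  Pixels outside the initializing box
are clamped to definite background and can never enter the foreground.

The min-cut runs through :func:`scipy.sparse.csgraph.maximum_flow` on
integer-scaled capacities; the residual graph yields the source-side
(foreground) partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .geometry import BoundingBox, Contour, Frame, signed_polygon_area

__all__ = [
    "TrimapLabel",
    "GmmModel",
    "GrabcutParams",
    "SegmentationResult",
    "SegmentationError",
    "InvalidBoxError",
    "EmptyRegionError",
    "NoBackgroundError",
    "init_trimap",
    "learn_gmm",
    "assign_components",
    "smoothness_beta",
    "grabcut_segment",
    "extract_contours",
]

# capacity quantization for the integer max-flow solver
_CAP_SCALE = float(2**16)


class SegmentationError(RuntimeError):
    pass


class InvalidBoxError(SegmentationError):
    pass


class EmptyRegionError(SegmentationError):
    pass


class NoBackgroundError(SegmentationError):
    pass


class TrimapLabel(enum.IntEnum):
    """Per-pixel prior labels constraining the segmentation."""

    DEFINITE_BACKGROUND = 0
    PROBABLE_BACKGROUND = 1
    PROBABLE_FOREGROUND = 2
    DEFINITE_FOREGROUND = 3


@dataclass(frozen=True)
class GmmModel:
    """K-component full-covariance Gaussian mixture over RGB color.

    ``weights`` lie on the simplex; covariances are kept SPD by adding
    ``cov_reg * I`` at estimation time.
    """

    weights: np.ndarray  # (K,)
    means: np.ndarray    # (K, 3)
    covariances: np.ndarray  # (K, 3, 3)

    @property
    def K(self) -> int:
        return int(self.weights.shape[0])

    def component_log_densities(self, pixels: np.ndarray) -> np.ndarray:
        """``(n, K)`` array of ``log(pi_k) + log N(z; mu_k, Sigma_k)``.

        Empty components (weight 0) get ``-inf``.
        """
        pixels = np.asarray(pixels, dtype=float)
        n = pixels.shape[0]
        out = np.full((n, self.K), -np.inf)
        for k in range(self.K):
            w = self.weights[k]
            if w <= 0:
                continue
            cov = self.covariances[k]
            chol = np.linalg.cholesky(cov)
            diff = pixels - self.means[k]
            sol = np.linalg.solve(chol, diff.T)  # (3, n)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = (
                np.log(w)
                - 0.5 * (maha + logdet + 3.0 * np.log(2.0 * np.pi))
            )
        return out

    def data_cost(self, pixels: np.ndarray) -> np.ndarray:
        """Per-pixel data term ``-max_k [log pi_k + log N_k]``."""
        return -np.max(self.component_log_densities(pixels), axis=1)


@dataclass(frozen=True)
class GrabcutParams:
    """Tunable segmentation parameters.

    ``K`` mixture components per side, smoothness weight ``gamma``, and the
    convergence rule (relative total-energy change below ``energy_rel_tol``
    or ``max_iters`` iterations, whichever first).
    """

    K: int = 5
    gamma: float = 50.0
    max_iters: int = 10
    energy_rel_tol: float = 1e-4
    cov_reg: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class SegmentationResult:
    """Binary foreground mask plus the per-iteration energy trace."""

    mask: np.ndarray
    energy_trace: list[float]
    iterations_run: int
    empty_foreground: bool = False


# ---------------------------------------------------------------------------
# trimap and GMM estimation
# ---------------------------------------------------------------------------

def init_trimap(subimage_shape: tuple[int, int], box: BoundingBox) -> np.ndarray:
    """Rectangle-initialized trimap: inside the box probable foreground,
    strictly outside definite background."""
    h, w = subimage_shape[:2]
    if box.xmin >= w or box.ymin >= h:
        raise InvalidBoxError(f"box {box} lies outside a {h}x{w} image")
    trimap = np.full((h, w), TrimapLabel.DEFINITE_BACKGROUND, dtype=np.uint8)
    trimap[box.ymin:min(box.ymax, h), box.xmin:min(box.xmax, w)] = (
        TrimapLabel.PROBABLE_FOREGROUND
    )
    return trimap


def learn_gmm(pixels: np.ndarray, assignments: np.ndarray, K: int,
              cov_reg: float = 1e-6) -> GmmModel:
    """Maximum-likelihood GMM estimate from hard component assignments.

    Component weight is the assigned fraction; mean/covariance are the
    sample statistics plus ``cov_reg * I``.  A component left empty is
    re-seeded deterministically by splitting the highest-weight component
    along its principal color axis.
    """
    pixels = np.asarray(pixels, dtype=float)
    assignments = np.asarray(assignments)
    if pixels.shape[0] == 0:
        raise EmptyRegionError("no pixels to estimate a GMM from")
    if assignments.shape[0] != pixels.shape[0]:
        raise ValueError("pixels and assignments disagree in length")
    if np.any((assignments < 0) | (assignments >= K)):
        raise ValueError("component index outside [0, K)")

    assignments = assignments.copy()
    # deterministically split the heaviest component into any empty slot
    for k in range(K):
        if np.sum(assignments == k) == 0:
            counts = np.bincount(assignments, minlength=K)
            j = int(np.argmax(counts))
            idx = np.flatnonzero(assignments == j)
            if idx.size < 2:
                continue  # nothing to split; leave component empty
            sub = pixels[idx]
            centered = sub - sub.mean(axis=0)
            cov = centered.T @ centered / idx.size
            _, vecs = np.linalg.eigh(cov)
            proj = centered @ vecs[:, -1]
            move = idx[proj > np.median(proj)]
            if move.size == 0 or move.size == idx.size:
                continue  # no color spread to split; leave component empty
            assignments[move] = k

    n = pixels.shape[0]
    weights = np.zeros(K)
    means = np.zeros((K, 3))
    covs = np.zeros((K, 3, 3))
    eye = np.eye(3)
    for k in range(K):
        sel = assignments == k
        cnt = int(np.sum(sel))
        weights[k] = cnt / n
        if cnt == 0:
            means[k] = 0.0
            covs[k] = eye
            continue
        sub = pixels[sel]
        means[k] = sub.mean(axis=0)
        centered = sub - means[k]
        covs[k] = centered.T @ centered / cnt + cov_reg * eye
    return GmmModel(weights, means, covs)


def assign_components(pixels: np.ndarray, fg_model: GmmModel, bg_model: GmmModel,
                      fg_mask: np.ndarray) -> np.ndarray:
    """Assign each pixel to the max-posterior component of its own side's
    model; ties break to the lowest component index."""
    pixels = np.asarray(pixels, dtype=float)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    out = np.zeros(pixels.shape[0], dtype=np.int64)
    if np.any(fg_mask):
        out[fg_mask] = np.argmax(
            fg_model.component_log_densities(pixels[fg_mask]), axis=1
        )
    if np.any(~fg_mask):
        out[~fg_mask] = np.argmax(
            bg_model.component_log_densities(pixels[~fg_mask]), axis=1
        )
    return out


# ---------------------------------------------------------------------------
# pairwise (smoothness) term
# ---------------------------------------------------------------------------

# offsets covering every unordered 8-neighbor pair once: (dy, dx)
_NEIGHBOR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _neighbor_pairs(shape: tuple[int, int]):
    """Flat index pairs (i, j) and inverse distances for all 8-neighbor
    unordered pairs of an ``h x w`` grid."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    ii, jj, inv_d = [], [], []
    for dy, dx in _NEIGHBOR_OFFSETS:
        if dx >= 0:
            a = idx[: h - dy, : w - dx]
            b = idx[dy:, dx:]
        else:
            a = idx[: h - dy, -dx:]
            b = idx[dy:, : w + dx]
        ii.append(a.ravel())
        jj.append(b.ravel())
        d = 1.0 if (dy == 0 or dx == 0) else 1.0 / np.sqrt(2.0)
        inv_d.append(np.full(a.size, d))
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(inv_d)


def smoothness_beta(subimage: np.ndarray) -> float:
    """``beta = 1 / (2 <||z_m - z_n||^2>)`` over all 8-neighbor pairs;
    0 for a constant image."""
    img = np.asarray(subimage, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w = img.shape[:2]
    if h * w < 2:
        raise SegmentationError("need at least 2 pixels")
    flat = img.reshape(h * w, -1)
    ii, jj, _ = _neighbor_pairs((h, w))
    sq = np.sum((flat[ii] - flat[jj]) ** 2, axis=1)
    mean_sq = float(np.mean(sq))
    if mean_sq == 0.0:
        return 0.0
    return 1.0 / (2.0 * mean_sq)


# ---------------------------------------------------------------------------
# min-cut
# ---------------------------------------------------------------------------

def _min_cut(fg_cost: np.ndarray, bg_cost: np.ndarray, clamp_bg: np.ndarray,
             ii: np.ndarray, jj: np.ndarray, pair_w: np.ndarray,
             gamma: float) -> np.ndarray:
    """Solve the binary labeling by s-t min-cut.

    ``fg_cost``/``bg_cost`` are per-pixel data terms for labeling a pixel
    foreground / background.  ``clamp_bg`` pixels are known background: they
    are removed from the graph outright (their incident pair weights fold
    into the neighbors' sink links), which enforces the hard constraint
    exactly without needing an "infinite" capacity.  Returns the boolean
    foreground mask (source side of the cut).

    The solver works on integers (and silently overflows above int32), so
    capacities are shifted per pixel (the cheaper side costs 0 — a
    labeling-independent constant), clipped (a clipped data cost still dwarfs
    the largest possible pairwise saving of ~8*gamma per pixel) and scaled
    adaptively so both every capacity and the min-cut value itself fit in
    31 bits.
    """
    n = fg_cost.size
    source, sink = n, n + 1

    shift = np.minimum(fg_cost, bg_cost)
    clip = max(1000.0, 100.0 * gamma)
    to_sink = np.minimum(fg_cost - shift, clip)      # cut when pixel is fg
    from_source = np.minimum(bg_cost - shift, clip)  # cut when pixel is bg

    i_clamped = clamp_bg[ii]
    j_clamped = clamp_bg[jj]
    only_i = i_clamped & ~j_clamped
    only_j = j_clamped & ~i_clamped
    np.add.at(to_sink, jj[only_i], pair_w[only_i])
    np.add.at(to_sink, ii[only_j], pair_w[only_j])
    keep_pair = ~(i_clamped | j_clamped)
    to_sink[clamp_bg] = 0.0
    from_source[clamp_bg] = 0.0

    pii, pjj, pw = ii[keep_pair], jj[keep_pair], pair_w[keep_pair]
    # the all-foreground and all-background labelings are feasible cuts, so
    # the min-cut value cannot exceed either total
    bound = max(1.0, min(float(np.sum(from_source)), float(np.sum(to_sink))))
    max_cap = max(1.0, float(to_sink.max(initial=0.0)),
                  float(from_source.max(initial=0.0)),
                  float(pw.max(initial=0.0)))
    scale = min(_CAP_SCALE, float(2**30) / max_cap, 0.9 * float(2**31) / bound)

    cap = np.concatenate([from_source, to_sink, pw, pw])
    rows = np.concatenate([np.full(n, source), np.arange(n), pii, pjj])
    cols = np.concatenate([np.arange(n), np.full(n, sink), pjj, pii])
    cap_int = np.round(cap * scale).astype(np.int64)
    keep = cap_int > 0
    graph = sparse.csr_matrix(
        (cap_int[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2)
    )
    result = maximum_flow(graph, source, sink)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    fg = np.zeros(n, dtype=bool)
    reachable = order[order < n]
    fg[reachable] = True
    fg[clamp_bg] = False
    return fg


def _total_energy(fg_cost: np.ndarray, bg_cost: np.ndarray, fg: np.ndarray,
                  ii: np.ndarray, jj: np.ndarray, pair_w: np.ndarray) -> float:
    data = float(np.sum(fg_cost[fg]) + np.sum(bg_cost[~fg]))
    cut = fg[ii] != fg[jj]
    return data + float(np.sum(pair_w[cut]))


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def grabcut_segment(subimage: np.ndarray, box: BoundingBox,
                    params: GrabcutParams | None = None) -> SegmentationResult:
    """Segment the object inside ``box`` out of ``subimage``.

    Parameters
    ----------
    subimage
        ``(h, w, 3)`` RGB array (any numeric dtype).
    box
        Initializing rectangle in subimage coordinates; everything strictly
        outside is clamped to background.
    params
        :class:`GrabcutParams`; defaults are K=5 components, gamma=50,
        at most 10 iterations.

    Returns
    -------
    SegmentationResult
        Boolean foreground mask of the subimage shape, the energy trace
        (one value per iteration, evaluated after the min-cut), and the
        number of iterations run.
    """
    if params is None:
        params = GrabcutParams()
    img = np.asarray(subimage, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise SegmentationError("subimage must be (h, w, 3) RGB")
    h, w = img.shape[:2]
    trimap = init_trimap((h, w), box)
    clamp_bg = (trimap == TrimapLabel.DEFINITE_BACKGROUND).ravel()
    if not np.any(clamp_bg):
        raise NoBackgroundError("box covers the entire image; no background sample")

    flat = img.reshape(-1, 3)
    fg = ~clamp_bg  # initial labeling: box interior = foreground

    beta = smoothness_beta(img)
    ii, jj, inv_d = _neighbor_pairs((h, w))
    color_sq = np.sum((flat[ii] - flat[jj]) ** 2, axis=1)
    pair_w = params.gamma * inv_d * np.exp(-beta * color_sq)

    # initial component assignments by seeded k-means per side
    from sklearn.cluster import KMeans

    assignments = np.zeros(h * w, dtype=np.int64)
    for side_mask in (fg, ~fg):
        px = flat[side_mask]
        k = min(params.K, max(1, len(np.unique(px, axis=0))))
        if len(px) <= params.K or k == 1:
            assignments[side_mask] = 0
        else:
            km = KMeans(n_clusters=k, n_init=1, random_state=params.seed)
            assignments[side_mask] = km.fit_predict(px)

    energy_trace: list[float] = []
    prev_energy = np.inf
    iterations = 0
    for it in range(params.max_iters):
        iterations = it + 1
        fg_any = bool(np.any(fg))
        if fg_any:
            fg_model = learn_gmm(flat[fg], assignments[fg], params.K, params.cov_reg)
        bg_model = learn_gmm(flat[~fg], assignments[~fg], params.K, params.cov_reg)
        if not fg_any:
            mask = np.zeros((h, w), dtype=bool)
            return SegmentationResult(mask, energy_trace, iterations,
                                      empty_foreground=True)

        fg_cost = fg_model.data_cost(flat)
        bg_cost = bg_model.data_cost(flat)

        fg = _min_cut(fg_cost, bg_cost, clamp_bg, ii, jj, pair_w, params.gamma)
        energy = _total_energy(fg_cost, bg_cost, fg, ii, jj, pair_w)
        energy_trace.append(energy)

        if not np.any(fg):
            return SegmentationResult(np.zeros((h, w), dtype=bool), energy_trace,
                                      iterations, empty_foreground=True)

        assignments = assign_components(flat, fg_model, bg_model, fg)

        if np.isfinite(prev_energy):
            denom = max(abs(prev_energy), 1e-12)
            if abs(prev_energy - energy) / denom < params.energy_rel_tol:
                break
        prev_energy = energy

    return SegmentationResult(fg.reshape(h, w), energy_trace, iterations)


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)

# screen-left turn preference at crack vertices keeps diagonally-touching
# pixels on a single outer loop (8-connectivity)
_TURN_ORDER = {
    (1, 0): ((0, -1), (1, 0), (0, 1)),    # east: north, east, south
    (-1, 0): ((0, 1), (-1, 0), (0, -1)),  # west: south, west, north
    (0, 1): ((1, 0), (0, 1), (-1, 0)),    # south: east, south, west
    (0, -1): ((-1, 0), (0, -1), (1, 0)),  # north: west, north, east
}


def _trace_component(mask: np.ndarray, x0: int, y0: int) -> list[np.ndarray]:
    """Closed crack-boundary loops of a binary component.

    Vertices lie on the pixel grid corners; pixel (r, c) occupies the unit
    cell [c, c+1) x [r, r+1).  ``x0, y0`` offset local coordinates back to
    the parent image.
    """
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    fg = padded
    # directed crack edges with foreground kept on a consistent side
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    rs, cs = np.nonzero(mask)
    for r, c in zip(rs, cs):
        pr, pc = r + 1, c + 1
        if not fg[pr - 1, pc]:  # bg above: east along top
            edges.setdefault((c, r), []).append((c + 1, r))
        if not fg[pr + 1, pc]:  # bg below: west along bottom
            edges.setdefault((c + 1, r + 1), []).append((c, r + 1))
        if not fg[pr, pc - 1]:  # bg left: north along left side
            edges.setdefault((c, r + 1), []).append((c, r))
        if not fg[pr, pc + 1]:  # bg right: south along right side
            edges.setdefault((c + 1, r), []).append((c + 1, r + 1))

    loops = []
    while edges:
        start = next(iter(edges))
        targets = edges[start]
        cur = start
        nxt = targets.pop()
        if not targets:
            del edges[start]
        loop = [start]
        while nxt != start:
            loop.append(nxt)
            dx, dy = nxt[0] - cur[0], nxt[1] - cur[1]
            targets = edges.get(nxt)
            if not targets:
                raise RuntimeError("open crack chain (corrupt mask?)")
            if len(targets) == 1:
                chosen = targets.pop()
            else:
                chosen = None
                for tdx, tdy in _TURN_ORDER[(dx, dy)]:
                    cand = (nxt[0] + tdx, nxt[1] + tdy)
                    if cand in targets:
                        chosen = cand
                        targets.remove(cand)
                        break
                if chosen is None:
                    chosen = targets.pop()
            if not targets:
                edges.pop(nxt, None)
            cur, nxt = nxt, chosen
        loops.append(np.asarray(loop, dtype=float) + [x0, y0])
    return loops


def _merge_collinear(vertices: np.ndarray) -> np.ndarray:
    prev = np.roll(vertices, 1, axis=0)
    nxt = np.roll(vertices, -1, axis=0)
    a = vertices - prev
    b = nxt - vertices
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return vertices[cross != 0]


def extract_contours(mask: np.ndarray, min_area: float = 16.0) -> list[Contour]:
    """Outer boundary polygon of every 8-connected foreground component.

    Vertices sit on pixel-boundary coordinates (pixel ``(r, c)`` spans the
    unit cell ``[c, c+1) x [r, r+1)``), collinear runs are merged, and the
    polygon is oriented counter-clockwise (positive shoelace sum in the
    x-right / y-down frame).  Components whose area falls below ``min_area``
    square pixels are dropped.  Interior holes are ignored.
    """
    mask = np.asarray(mask).astype(bool)
    if not np.any(mask):
        return []
    labels, nlab = ndimage.label(mask, structure=_EIGHT)
    contours = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, nlab + 1)):
        comp = labels[sl] == lab
        y0, x0 = sl[0].start, sl[1].start
        loops = _trace_component(comp, x0, y0)
        # the outer boundary is the loop of largest absolute area
        best = max(loops, key=lambda v: abs(signed_polygon_area(v)))
        area = abs(signed_polygon_area(best))
        if area < min_area:
            continue
        if signed_polygon_area(best) < 0:
            best = best[::-1]
        best = _merge_collinear(best)
        contours.append(Contour(best, Frame.IMAGE))
    return contours
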