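"""Per-slice lung segmentation with a parametric active contour (snake).

Each axial slice is thresholded at an air-density HU value to seed one
initial contour per body-enclosed low-density component; each contour is
then evolved by minimizing the classic snake energy

    E = sum_i [ alpha*|x_{i+1}-x_i|^2 + beta*|x_{i+1}-2x_i+x_{i-1}|^2 ]
        - kappa_ext * sum_i edge(x_i),        edge = |grad(G_sigma * I)|^2

with a semi-implicit update: the internal (elasticity + rigidity) terms are
inverted exactly via a circulant system, the external image force is applied
explicitly.  Candidate steps that would raise the total energy are rejected
and retried with a smaller step, so the energy is non-increasing by
construction and evolution is fully deterministic.

The rasterized contours of all slices form the lung mask; the conducting
airway lumen (trachea and main bronchi, tracked by :mod:`airtrapcad.airway`)
is subtracted so that air trapped in the parenchyma, not air in the airway,
drives the downstream features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.linalg import lu_factor, lu_solve
from skimage import draw, measure, segmentation as sk_seg

from .errors import ContourCollapseError, ParameterError, SegmentationError
from .io_ct import CTVolume, LungMask

logger = logging.getLogger("airtrapcad.segmentation")

#: Default HU threshold separating air-filled lung from soft tissue.
DEFAULT_AIR_THRESHOLD = -320.0
#: Components smaller than this physical area are treated as noise at seeding.
MIN_COMPONENT_AREA_MM2 = 50.0
#: A contour whose enclosed area falls below this (px^2) has collapsed.
MIN_CONTOUR_AREA_PX = 10.0


@dataclass
class SnakeParams:
    """Weights and stopping rules of the active-contour evolution.

    alpha, beta
        Elasticity (stretch) and rigidity (curvature) weights of the
        internal energy, both >= 0.
    gamma
        Evolution step size (> 0); automatically reduced within an
        iteration whenever a step would increase the energy.
    kappa_ext
        Weight of the external image force (>= 0).
    sigma
        Gaussian smoothing (px) applied to the slice before the edge map.
    max_iter, conv_tol
        Evolution stops when the mean point displacement per iteration
        drops below ``conv_tol`` (px) or after ``max_iter`` iterations.
    """

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 2.0
    kappa_ext: float = 2.0
    sigma: float = 2.0
    max_iter: int = 500
    conv_tol: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "kappa_ext"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if int(self.max_iter) < 1:
            raise ParameterError(f"max_iter must be >= 1, got {self.max_iter}")
        self.max_iter = int(self.max_iter)
        if self.conv_tol < 0:
            raise ParameterError(f"conv_tol must be >= 0, got {self.conv_tol}")


@dataclass
class Contour:
    """Closed polyline of (row, col) points, sub-voxel precision allowed."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ParameterError("contour points must be an (N, 2) array")
        if len(self.points) < 8:
            raise ParameterError("a contour needs at least 8 points")

    def area(self) -> float:
        """Enclosed area (px^2) by the shoelace formula."""
        r, c = self.points[:, 0], self.points[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def __len__(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------------
# Seeding

def _resample_closed(points: np.ndarray, step: float = 2.0) -> np.ndarray:
    """Resample a closed polyline at uniform arclength spacing (>= 16 points)."""
    if np.allclose(points[0], points[-1]):
        points = points[:-1]
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(16, int(round(total / step)))
    t = np.linspace(0.0, total, n, endpoint=False)
    r = np.interp(t, arclen, closed[:, 0])
    c = np.interp(t, arclen, closed[:, 1])
    return np.column_stack([r, c])


def seed_contours(
    slice_hu: np.ndarray,
    air_threshold: float = DEFAULT_AIR_THRESHOLD,
    spacing_yx: Tuple[float, float] = (1.0, 1.0),
    min_area_mm2: float = MIN_COMPONENT_AREA_MM2,
) -> List[Contour]:
    """Initial contours around body-enclosed air components of one slice.

    Components touching the image border (background air around the body)
    and components below ``min_area_mm2`` are discarded.  Returns an empty
    list when no candidate exists; that is not an error.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    air = slice_hu < air_threshold
    air = sk_seg.clear_border(air)
    labels, n = ndimage.label(air)
    if n == 0:
        return []
    dy, dx = spacing_yx
    contours: List[Contour] = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if comp.sum() * dy * dx < min_area_mm2:
            continue
        traced = measure.find_contours(comp.astype(float), 0.5)
        if not traced:
            continue
        boundary = max(traced, key=len)
        contours.append(Contour(_resample_closed(boundary)))
    return contours


# --------------------------------------------------------------------------
# Evolution

def edge_map(slice_hu: np.ndarray, sigma: float) -> np.ndarray:
    """Squared gradient magnitude of the Gaussian-smoothed slice.

    Normalized to a maximum of 1 so the external-force weight is
    independent of the image's intensity scale (HU offsets and contrast
    do not change the evolution).
    """
    g = ndimage.gaussian_filter(np.asarray(slice_hu, dtype=float), sigma)
    gr, gc = np.gradient(g)
    e = gr**2 + gc**2
    peak = e.max()
    return e / peak if peak > 0 else e


def _interp(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(field, pts.T, order=1, mode="nearest")


def snake_energy(
    pts: np.ndarray, edge: np.ndarray, p: SnakeParams
) -> float:
    """Total snake energy (internal minus weighted edge attraction)."""
    d1 = np.roll(pts, -1, axis=0) - pts
    d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
    e_int = p.alpha * float((d1**2).sum()) + p.beta * float((d2**2).sum())
    e_ext = -p.kappa_ext * float(_interp(edge, pts).sum())
    return e_int + e_ext


def _internal_gradient_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Gradient operator of the internal energy: 2*(alpha*K2 + beta*K2@K2)."""
    eye = np.eye(n)
    shift = np.roll(eye, 1, axis=0)
    k2 = 2 * eye - shift - shift.T
    return 2.0 * (alpha * k2 + beta * (k2 @ k2))


def evolve_snake(
    slice_hu: np.ndarray,
    c0: Contour,
    p: SnakeParams,
    edge: Optional[np.ndarray] = None,
    energy_log: Optional[list] = None,
) -> Contour:
    """Evolve one contour to a (local) minimum of the snake energy.

    Semi-implicit update per iteration: internal forces are handled by the
    prefactored circulant system, the external force (gradient ascent on the
    edge map) explicitly.  A candidate step that would increase the total
    energy is retried with the step size halved; if no decreasing step can
    be found the contour is at a discrete minimum and evolution stops.

    Raises
    ------
    ContourCollapseError
        If the enclosed area falls below the minimum contour size.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    if not np.all(np.isfinite(slice_hu)):
        raise ParameterError("slice contains non-finite values")
    if edge is None:
        edge = edge_map(slice_hu, p.sigma)
    f_r, f_c = np.gradient(edge)

    x = c0.points.copy()
    n = len(x)
    a_grad = _internal_gradient_matrix(n, p.alpha, p.beta)
    factor_cache = {}

    def factors(gamma_eff: float):
        if gamma_eff not in factor_cache:
            factor_cache[gamma_eff] = lu_factor(np.eye(n) + gamma_eff * a_grad)
        return factor_cache[gamma_eff]

    max_r, max_c = slice_hu.shape[0] - 1, slice_hu.shape[1] - 1
    energy = snake_energy(x, edge, p)
    if energy_log is not None:
        energy_log.append(energy)
    iterations = 0
    for _ in range(p.max_iter):
        force = p.kappa_ext * np.column_stack([_interp(f_r, x), _interp(f_c, x)])
        accepted = False
        gamma_eff = p.gamma
        for _try in range(12):
            cand = lu_solve(factors(gamma_eff), x + gamma_eff * force)
            cand[:, 0] = np.clip(cand[:, 0], 0.0, max_r)
            cand[:, 1] = np.clip(cand[:, 1], 0.0, max_c)
            cand_energy = snake_energy(cand, edge, p)
            if cand_energy <= energy + 1e-12:
                accepted = True
                break
            gamma_eff *= 0.5
        if not accepted:  # discrete local minimum
            break
        disp = float(np.mean(np.linalg.norm(cand - x, axis=1)))
        x, energy = cand, cand_energy
        if energy_log is not None:
            energy_log.append(energy)
        iterations += 1
        area = Contour(x).area()
        if area < MIN_CONTOUR_AREA_PX:
            raise ContourCollapseError(
                f"contour collapsed to {area:.1f} px^2 after {iterations} iterations"
            )
        if disp < p.conv_tol:
            break
    logger.debug("snake converged in %d iterations (E=%.3g)", iterations, energy)
    return Contour(x)


# --------------------------------------------------------------------------
# Volume segmentation

def rasterize_contour(c: Contour, shape: Tuple[int, int]) -> np.ndarray:
    """Filled binary region enclosed by a contour."""
    rr, cc = draw.polygon(c.points[:, 0], c.points[:, 1], shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def segment_lungs(
    v: CTVolume,
    params: Optional[SnakeParams] = None,
    air_threshold: float = DEFAULT_AIR_THRESHOLD,
    airway_track=None,
    per_lung: bool = False,
):
    """Segment the lung parenchyma of a whole volume.

    Runs seed + snake on every axial slice, rasterizes the final contours
    and subtracts the tracked airway lumen.  If ``airway_track`` is None
    the trachea is tracked internally; a volume with no trackable airway
    (e.g. a synthetic two-ellipsoid field) is segmented without exclusion.

    With ``per_lung=True`` returns ``(left, right)`` masks split by the
    mediastinal midline of each connected component's centroid; otherwise a
    single merged :class:`LungMask`.
    """
    params = params or SnakeParams()
    dz, dy, dx = v.spacing
    mask = np.zeros(v.shape, dtype=bool)
    for k in range(v.n_slices):
        slice_hu = v.voxels[k]
        seeds = seed_contours(slice_hu, air_threshold, (dy, dx))
        if not seeds:
            continue
        edge = edge_map(slice_hu, params.sigma)
        for c0 in seeds:
            try:
                c = evolve_snake(slice_hu, c0, params, edge=edge)
            except ContourCollapseError:
                logger.warning("slice %d: contour collapsed, dropped", k)
                continue
            mask[k] |= rasterize_contour(c, slice_hu.shape)

    if airway_track is None:
        from .airway import track_trachea
        from .errors import AirwayTrackingError

        try:
            airway_track = track_trachea(v, air_threshold)
        except AirwayTrackingError:
            airway_track = None
    if airway_track is not None:
        lumen = ndimage.binary_dilation(airway_track.lumen_mask, iterations=1)
        mask &= ~lumen

    if not mask.any():
        raise SegmentationError(
            f"no lung component found in any slice of subject {v.subject_id!r}"
        )
    if per_lung:
        return _split_lungs(mask, v)
    return LungMask(mask.astype(np.uint8), v.spacing, v.phase, v.subject_id)


def _split_lungs(mask: np.ndarray, v: CTVolume):
    labels, n = ndimage.label(mask)
    mid = mask.shape[2] / 2.0
    left = np.zeros_like(mask)
    right = np.zeros_like(mask)
    for lbl in range(1, n + 1):
        comp = labels == lbl
        col = ndimage.center_of_mass(comp)[2]
        (left if col < mid else right)[comp] = True
    return (
        LungMask(left.astype(np.uint8), v.spacing, v.phase, v.subject_id),
        LungMask(right.astype(np.uint8), v.spacing, v.phase, v.subject_id),
    )
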