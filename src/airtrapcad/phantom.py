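"""Synthetic paired inspiration/expiration CT phantoms and cohort simulation.

The phantom emulates the anatomy the pipeline depends on: an elliptical
soft-tissue torso (0 HU) in background air (-1000 HU) containing two
air-filled lung ellipsoids (-850 HU at inspiration) and a tracheal tube
that bifurcates into two main bronchi at a known slice.  The expiration
phase shrinks both lungs about their centroids by an in-plane factor
``s_xy`` and an axial factor ``s_z`` and renders them denser (default
+100 HU), mimicking the expiratory attenuation increase of real lungs, so
the segmentation is exercised under a phase-dependent intensity shift.

Ground truth is known analytically: the normalized area variation at a
fixed mid-lung cut is ``1 - s_xy**2`` and the normalized volume variation
is ``1 - s_xy**2 * s_z``.  Both are recorded in the metadata together with
per-slice truth areas and voxel-counted truth volumes.

The cohort simulator draws (dS_N, dV_N) feature pairs per subject from
class-conditional bivariate Gaussians whose default means and standard
deviations are the published summary statistics of the 12-normal /
25-patient study cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import InputError, ParameterError
from .io_ct import EXPIRATION, INSPIRATION, CTVolume, LungMask

# Published cohort summary statistics: per class, (mean, SD) of the area
# variation dS_N and the volume variation dV_N.
COHORT_NORMAL = {"delta_S_N": (0.3711, 0.0825), "delta_V_N": (0.4121, 0.0762)}
COHORT_PATIENT = {"delta_S_N": (0.1749, 0.2341), "delta_V_N": (0.1996, 0.1981)}
COHORT_N_NORMAL = 12
COHORT_N_PATIENT = 25


@dataclass
class PhantomSpec:
    """Parameters of the digital thorax phantom.

    Defaults describe an adult thorax scanned apex-to-base at the study's
    3 mm slice thickness and 1 mm in-plane resolution: a ~29 cm z-range,
    22 cm-tall lungs and a carina about one third of the way down.
    """

    shape: Tuple[int, int, int] = (96, 192, 192)  # (slices, rows, cols)
    spacing: Tuple[float, float, float] = (3.0, 1.0, 1.0)  # (dz, dy, dx) mm
    body_semiaxes_mm: Tuple[float, float] = (74.0, 90.0)  # (y, x)
    lung_semiaxes_mm: Tuple[float, float, float] = (110.0, 55.0, 30.0)  # (z, y, x)
    lung_center_offset_mm: float = 46.0  # |x| of each lung centre
    lung_center_slice: int = 48
    lung_hu: float = -850.0
    body_hu: float = 0.0
    background_hu: float = -1000.0
    airway_hu: float = -1000.0
    trachea_radius_mm: float = 8.0
    bronchus_radius_mm: float = 5.5
    bronchus_offset_mm: float = 8.5  # |x| of each bronchus axis
    bifurcation_slice: int = 44
    bronchus_extent_slices: int = 13
    s_xy: float = 1.0
    s_z: float = 1.0
    expiration_hu_offset: float = 100.0
    noise_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ParameterError(f"invalid phantom shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if not (0 < self.s_xy <= 1 and 0 < self.s_z <= 1):
            raise ParameterError(
                f"expiratory scales must lie in (0, 1], got s_xy={self.s_xy}, s_z={self.s_z}"
            )
        if not (0 <= self.bifurcation_slice < self.shape[0]):
            raise ParameterError(
                f"bifurcation_slice {self.bifurcation_slice} outside grid of {self.shape[0]} slices"
            )
        if self.trachea_radius_mm <= 0 or self.bronchus_radius_mm <= 0:
            raise ParameterError("airway radii must be positive")
        if min(self.lung_semiaxes_mm) <= 0:
            raise ParameterError("lung semi-axes must be positive")
        # Airway must stay clear of the lungs: the lungs' inner x-extent has
        # to exceed both the tracheal radius and the bronchial outer edge.
        inner = self.lung_center_offset_mm - self.lung_semiaxes_mm[2]
        outer_airway = max(
            self.trachea_radius_mm, self.bronchus_offset_mm + self.bronchus_radius_mm
        )
        if inner <= outer_airway:
            raise ParameterError(
                "lungs overlap the airway: inner lung edge at "
                f"{inner:.1f} mm vs airway extent {outer_airway:.1f} mm"
            )
        by, bx = self.body_semiaxes_mm
        # Ellipse-in-ellipse containment: the widest lung cross-section must
        # stay strictly inside the torso ellipse (margin keeps the soft-tissue
        # rim thick enough that noise cannot bridge lung air to background).
        theta = np.linspace(0.0, 2 * math.pi, 721)
        yb = self.lung_semiaxes_mm[1] * np.sin(theta)
        xb = self.lung_center_offset_mm + self.lung_semiaxes_mm[2] * np.cos(theta)
        if np.max((yb / by) ** 2 + (xb / bx) ** 2) > 0.95:
            raise ParameterError("lungs do not fit inside the body envelope")

    @property
    def true_delta_S_N(self) -> float:
        return 1.0 - self.s_xy**2

    @property
    def true_delta_V_N(self) -> float:
        return 1.0 - self.s_xy**2 * self.s_z


def _grids(spec: PhantomSpec):
    """Physical (z, y, x) coordinate grids in mm, origin at the grid centre in-plane."""
    ns, nr, nc = spec.shape
    dz, dy, dx = spec.spacing
    z = np.arange(ns)[:, None, None] * dz
    y = (np.arange(nr)[None, :, None] - (nr - 1) / 2.0) * dy
    x = (np.arange(nc)[None, None, :] - (nc - 1) / 2.0) * dx
    return z, y, x


def _lung_masks(spec: PhantomSpec, s_xy: float, s_z: float) -> np.ndarray:
    """Boolean union of the two lung ellipsoids at the given shrink factors."""
    z, y, x = _grids(spec)
    az, ay, ax = spec.lung_semiaxes_mm
    az, ay, ax = az * s_z, ay * s_xy, ax * s_xy
    cz = spec.lung_center_slice * spec.spacing[0]
    mask = np.zeros(spec.shape, dtype=bool)
    for cx in (-spec.lung_center_offset_mm, spec.lung_center_offset_mm):
        mask |= ((z - cz) / az) ** 2 + (y / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
    return mask


def _airway_mask(spec: PhantomSpec) -> np.ndarray:
    """Trachea down to the bifurcation, then two parallel main bronchi."""
    z, y, x = _grids(spec)
    ns = spec.shape[0]
    sl = np.arange(ns)[:, None, None]
    mask = np.zeros(spec.shape, dtype=bool)
    trachea = (y**2 + x**2 <= spec.trachea_radius_mm**2) & (sl < spec.bifurcation_slice)
    mask |= np.broadcast_to(trachea, spec.shape)
    b_end = min(ns, spec.bifurcation_slice + spec.bronchus_extent_slices)
    in_b = (sl >= spec.bifurcation_slice) & (sl < b_end)
    for cx in (-spec.bronchus_offset_mm, spec.bronchus_offset_mm):
        tube = (y**2 + (x - cx) ** 2 <= spec.bronchus_radius_mm**2) & in_b
        mask |= np.broadcast_to(tube, spec.shape)
    return mask


def _render_phase(spec: PhantomSpec, phase: str, rng: np.random.Generator):
    s_xy, s_z = (1.0, 1.0) if phase == INSPIRATION else (spec.s_xy, spec.s_z)
    _, y, x = _grids(spec)
    by, bx = spec.body_semiaxes_mm
    body = np.broadcast_to((y / by) ** 2 + (x / bx) ** 2 <= 1.0, spec.shape)

    hu = np.full(spec.shape, spec.background_hu, dtype=np.float32)
    hu[body] = spec.body_hu
    lungs = _lung_masks(spec, s_xy, s_z)
    lung_hu = spec.lung_hu + (spec.expiration_hu_offset if phase == EXPIRATION else 0.0)
    hu[lungs] = lung_hu
    airway = _airway_mask(spec)
    if np.any(airway & lungs):
        raise ParameterError("airway tubes intersect the lung ellipsoids")
    hu[airway] = spec.airway_hu
    if spec.noise_sigma > 0:
        hu += rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)
    return hu, lungs


def generate_phantom_pair(spec: PhantomSpec):
    """Render the inspiration/expiration phantom pair with ground truth.

    Returns
    -------
    (vol_insp, vol_exp, truth_insp, truth_exp, metadata)
        CT volumes, binary truth lung masks, and a metadata dict with the
        analytic feature values, per-slice truth areas (mm^2) and truth
        volumes (mm^3).  Identical specs (including seed) render
        bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    hu_i, lungs_i = _render_phase(spec, INSPIRATION, rng)
    hu_e, lungs_e = _render_phase(spec, EXPIRATION, rng)
    dz, dy, dx = spec.spacing
    vox = dz * dy * dx

    vol_i = CTVolume(hu_i, spec.spacing, INSPIRATION, subject_id="phantom")
    vol_e = CTVolume(hu_e, spec.spacing, EXPIRATION, subject_id="phantom")
    m_i = LungMask(lungs_i.astype(np.uint8), spec.spacing, INSPIRATION, "phantom")
    m_e = LungMask(lungs_e.astype(np.uint8), spec.spacing, EXPIRATION, "phantom")

    az, ay, ax = spec.lung_semiaxes_mm
    analytic_v_i = 2 * (4.0 / 3.0) * math.pi * az * ay * ax
    meta = {
        "true_delta_S_N": spec.true_delta_S_N,
        "true_delta_V_N": spec.true_delta_V_N,
        "bifurcation_slice": spec.bifurcation_slice,
        "slice_areas_insp_mm2": (lungs_i.sum(axis=(1, 2)) * dy * dx).tolist(),
        "slice_areas_exp_mm2": (lungs_e.sum(axis=(1, 2)) * dy * dx).tolist(),
        "truth_volume_insp_mm3": float(lungs_i.sum()) * vox,
        "truth_volume_exp_mm3": float(lungs_e.sum()) * vox,
        "analytic_volume_insp_mm3": analytic_v_i,
        "analytic_volume_exp_mm3": analytic_v_i * spec.s_xy**2 * spec.s_z,
    }
    return vol_i, vol_e, m_i, m_e, meta


def generate_cohort_features(
    n_normal: int,
    n_patient: int,
    params: Optional[Dict[str, Dict[str, Tuple[float, float]]]] = None,
    correlation: float = 0.8,
    seed: int = 0,
) -> List["FeatureRecord"]:
    """Draw per-subject (dS_N, dV_N) pairs from class-conditional Gaussians.

    ``params`` maps class label -> {"delta_S_N": (mu, sd), "delta_V_N":
    (mu, sd)}; defaults are the published cohort summaries.  ``correlation``
    is the within-subject correlation between the two features (the strong
    area-volume coupling of real lungs).
    """
    from .features import FeatureRecord  # deferred: features imports io_ct only

    if n_normal < 1 or n_patient < 1:
        raise ParameterError("need at least one subject per class")
    if not (-1.0 < correlation < 1.0):
        raise ParameterError(f"correlation must lie in (-1, 1), got {correlation}")
    defaults = {"normal": COHORT_NORMAL, "patient": COHORT_PATIENT}
    if params:
        defaults = {**defaults, **params}

    rng = np.random.default_rng(seed)
    records: List[FeatureRecord] = []
    for label, n in (("normal", n_normal), ("patient", n_patient)):
        (mu_s, sd_s) = defaults[label]["delta_S_N"]
        (mu_v, sd_v) = defaults[label]["delta_V_N"]
        cov = np.array(
            [
                [sd_s**2, correlation * sd_s * sd_v],
                [correlation * sd_s * sd_v, sd_v**2],
            ]
        )
        draws = rng.multivariate_normal([mu_s, mu_v], cov, size=n)
        for i, (ds, dv) in enumerate(draws):
            records.append(
                FeatureRecord(
                    subject_id=f"{label}_{i:05d}",
                    delta_S_N=float(ds),
                    delta_V_N=float(dv),
                    label=label,
                )
            )
    return records
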