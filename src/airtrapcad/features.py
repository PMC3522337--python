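"""Air-trapping features: normalized area and volume variation.

Air trapping in COPD shows as a reduced decrease of lung size from full
inspiration to full expiration.  Two features quantify it:

* ``delta_S_N`` — area variation at the carina cut, ``(S_insp - S_exp) /
  S_insp``, each phase's area taken at its own carina slice.  Dividing by
  the inspiration area removes the subject's size (age/height/sex) from
  the measurement.
* ``delta_V_N`` — total lung volume variation, ``(V_insp - V_exp) /
  V_insp``.  To cut computation the volume may be estimated from every
  k-th slice (default k=17), each sampled slice standing in for the k
  slice-thicknesses below it.

Healthy lungs empty substantially (both features near 0.4 in the reference
cohort); trapped air keeps them low.  Negative values (expiration larger
than inspiration) are physiologically odd but kept and logged, never
clamped, so the downstream Gaussian class models see the data as measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .airway import detect_carina, track_trachea
from .errors import AirTrapError, DegenerateInputError, ParameterError
from .io_ct import CTVolume, LungMask
from .segmentation import DEFAULT_AIR_THRESHOLD, SnakeParams, segment_lungs

logger = logging.getLogger("airtrapcad.features")

DEFAULT_SUBSAMPLE_STEP = 17


@dataclass
class FeatureRecord:
    """Per-subject feature pair with an optional class label."""

    subject_id: str
    delta_S_N: float
    delta_V_N: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in ("normal", "patient", "unknown"):
            raise ParameterError(f"label must be normal/patient/unknown, got {self.label!r}")
        for name in ("delta_S_N", "delta_V_N"):
            v = getattr(self, name)
            if v != v or v in (float("inf"), float("-inf")):
                raise ParameterError(f"{name} must be finite, got {v}")
            if v < 0:
                logger.warning(
                    "subject %s: negative %s = %.4f (expiration larger than inspiration)",
                    self.subject_id, name, v,
                )


def lung_area(mask: LungMask, slice_index: int) -> float:
    """Physical lung cross-section (mm^2) of one slice of the mask."""
    if not (0 <= slice_index < mask.n_slices):
        raise IndexError(
            f"slice {slice_index} out of range for {mask.n_slices}-slice mask"
        )
    _, dy, dx = mask.spacing
    return float(mask.voxels[slice_index].sum()) * dy * dx


def area_variation(
    mask_insp: LungMask,
    mask_exp: LungMask,
    carina_insp: int,
    carina_exp: int,
) -> float:
    """Normalized area variation dS_N = (S_insp - S_exp) / S_insp.

    Areas are taken at each phase's own carina slice.
    """
    s_i = lung_area(mask_insp, carina_insp)
    if s_i <= 0:
        raise DegenerateInputError("inspiration carina-slice area is zero")
    s_e = lung_area(mask_exp, carina_exp)
    return (s_i - s_e) / s_i


def _subsampled_volume(mask: LungMask, k: int) -> float:
    """Volume (mm^3) from slices {0, k, 2k, ...}, each weighted by the
    number of slice-thicknesses it represents (k, truncated at the end)."""
    dz, dy, dx = mask.spacing
    n = mask.n_slices
    total = 0.0
    for i in range(0, n, k):
        weight = min(k, n - i) * dz
        total += float(mask.voxels[i].sum()) * dy * dx * weight
    return total


def volume_variation(
    mask_insp: LungMask,
    mask_exp: LungMask,
    subsample_step: int = DEFAULT_SUBSAMPLE_STEP,
) -> float:
    """Normalized volume variation dV_N = (V_insp - V_exp) / V_insp.

    With ``subsample_step`` k=1 the volumes are exact mask volumes; larger
    k estimates them from every k-th slice.
    """
    k = int(subsample_step)
    if k < 1:
        raise ParameterError(f"subsample_step must be >= 1, got {subsample_step}")
    v_i = _subsampled_volume(mask_insp, k)
    if v_i <= 0:
        raise DegenerateInputError("inspiration mask volume is zero")
    v_e = _subsampled_volume(mask_exp, k)
    return (v_i - v_e) / v_i


class StageError(AirTrapError):
    """A pipeline stage failed for one subject; names the stage."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed for subject {subject_id!r}: {cause}")


def extract_features(
    vol_insp: CTVolume,
    vol_exp: CTVolume,
    snake_params: Optional[SnakeParams] = None,
    air_threshold: float = DEFAULT_AIR_THRESHOLD,
    subsample_step: int = DEFAULT_SUBSAMPLE_STEP,
    label: str = "unknown",
) -> FeatureRecord:
    """Run segmentation, airway tracking and carina detection on both
    phases and return the (dS_N, dV_N) feature pair.

    Stage failures propagate as :class:`StageError` tagged with the failing
    stage name.
    """
    sid = vol_insp.subject_id or vol_exp.subject_id
    results = {}
    for name, vol in (("inspiration", vol_insp), ("expiration", vol_exp)):
        try:
            track = track_trachea(vol, air_threshold)
        except AirTrapError as exc:
            raise StageError(f"airway-tracking/{name}", sid, exc) from exc
        try:
            mask = segment_lungs(vol, snake_params, air_threshold, airway_track=track)
        except AirTrapError as exc:
            raise StageError(f"segmentation/{name}", sid, exc) from exc
        try:
            carina = detect_carina(track)
        except AirTrapError as exc:
            raise StageError(f"carina-detection/{name}", sid, exc) from exc
        results[name] = (mask, carina)

    mask_i, carina_i = results["inspiration"]
    mask_e, carina_e = results["expiration"]
    try:
        ds = area_variation(mask_i, mask_e, carina_i, carina_e)
        dv = volume_variation(mask_i, mask_e, subsample_step)
    except AirTrapError as exc:
        raise StageError("features", sid, exc) from exc
    return FeatureRecord(subject_id=sid, delta_S_N=ds, delta_V_N=dv, label=label)
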