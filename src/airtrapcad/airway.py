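"""Tracheal air-column tracking and carina (bifurcation) detection.

The trachea is the single air-filled tube visible in the most superior
slices of a thoracic scan.  Tracking seeds there and follows spatially
overlapping air components slice by slice toward the lung base, recording
each component's centroid and physical area.  The carina — the ridge where
the trachea splits into the right and left main bronchi — is the most
superior slice at which the tracked column has split into two or more
components that persist, and it anchors the 2-D area-variation feature
(the same anatomical cut is found independently at inspiration and at
expiration).  The tracked lumen is also what the segmentation subtracts
from the lung mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import segmentation as sk_seg

from .errors import AirwayTrackingError, CarinaNotFoundError
from .io_ct import CTVolume

#: Plausible cross-sectional area range of the tracheal/bronchial lumen.
MIN_LUMEN_AREA_MM2 = 50.0
MAX_LUMEN_AREA_MM2 = 500.0
#: A seed component must stay trackable this many consecutive slices; a
#: lung apex cap grows past the plausible lumen area within 1-2 slices and
#: is rejected, so only a true airway can seed the track.
SEED_PERSISTENCE_SLICES = 5


@dataclass
class TrackedComponent:
    """One airway lumen cross-section: centroid in (row, col) px and area in mm^2."""

    centroid: Tuple[float, float]
    area_mm2: float


@dataclass
class AirwayTrack:
    """Per-slice airway components plus the rasterized lumen.

    ``components[k]`` lists the tracked lumen cross-sections of slice ``k``
    (empty above the seed slice and below the track end).  ``lumen_mask``
    is the boolean union of all tracked component pixels, aligned with the
    source volume.
    """

    components: List[List[TrackedComponent]]
    lumen_mask: np.ndarray
    seed_slice: int
    spacing: Tuple[float, float, float]

    @property
    def n_slices(self) -> int:
        return len(self.components)

    def counts(self) -> List[int]:
        return [len(c) for c in self.components]


def _slice_components(slice_hu, air_threshold, dy, dx):
    """Body-enclosed air components of one slice with centroid/area/pixels."""
    air = sk_seg.clear_border(np.asarray(slice_hu) < air_threshold)
    labels, n = ndimage.label(air)
    out = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        area = float(comp.sum()) * dy * dx
        r, c = ndimage.center_of_mass(comp)
        out.append(((r, c), area, comp))
    return out


def _plausible(comps):
    return [c for c in comps if MIN_LUMEN_AREA_MM2 <= c[1] <= MAX_LUMEN_AREA_MM2]


def track_trachea(v: CTVolume, air_threshold: float = -320.0) -> AirwayTrack:
    """Track the airway lumen from the apex to where it ends.

    Seeds from the first slice in the top 10% of the volume that holds at
    least one plausible lumen component (area 50-500 mm^2) persisting for
    several consecutive slices, then follows overlapping components
    inferiorly until none overlap or the volume ends.

    Raises
    ------
    AirwayTrackingError
        If no plausible tracheal component exists in the top decile.
    """
    n_slices = v.n_slices
    _, dy, dx = v.spacing
    top = max(1, math.ceil(0.1 * n_slices))

    cache = {}

    def comps(k):
        if k not in cache:
            cache[k] = _slice_components(v.voxels[k], air_threshold, dy, dx)
        return cache[k]

    def follow(pixels, k):
        """Components of slice k overlapping the given pixel set, lumen-sized."""
        return [c for c in comps(k) if (c[2] & pixels).any() and c[1] <= MAX_LUMEN_AREA_MM2]

    seed_slice = None
    for s in range(top):
        cand = _plausible(comps(s))
        if not cand:
            continue
        pixels = np.logical_or.reduce([c[2] for c in cand])
        ok = True
        for t in range(s + 1, min(s + SEED_PERSISTENCE_SLICES, n_slices)):
            nxt = follow(pixels, t)
            if not nxt:
                ok = False
                break
            pixels = np.logical_or.reduce([c[2] for c in nxt])
        if ok:
            seed_slice = s
            break
    if seed_slice is None:
        raise AirwayTrackingError(
            f"no tracheal component (area {MIN_LUMEN_AREA_MM2:.0f}-"
            f"{MAX_LUMEN_AREA_MM2:.0f} mm^2) in the top {top} slices"
        )

    components: List[List[TrackedComponent]] = [[] for _ in range(n_slices)]
    lumen = np.zeros(v.shape, dtype=bool)
    current = _plausible(comps(seed_slice))
    pixels = np.logical_or.reduce([c[2] for c in current])
    for k in range(seed_slice, n_slices):
        if k > seed_slice:
            current = follow(pixels, k)
            if not current:
                break
            pixels = np.logical_or.reduce([c[2] for c in current])
        for (cent, area, comp) in current:
            components[k].append(TrackedComponent(cent, area))
            lumen[k] |= comp
    return AirwayTrack(components, lumen, seed_slice, v.spacing)


def detect_carina(track: AirwayTrack) -> int:
    """Most superior slice where the tracked airway has split durably.

    Returns the smallest slice index at which the track holds >= 2
    components and the following two slices do as well (a single-slice
    noise split must not register as the carina).

    Raises
    ------
    CarinaNotFoundError
        If the airway never bifurcates.
    """
    counts = track.counts()
    n = len(counts)
    for k in range(track.seed_slice, n):
        if counts[k] >= 2:
            persist = range(k + 1, min(k + 3, n))
            if all(counts[t] >= 2 for t in persist):
                return k
    raise CarinaNotFoundError("tracked airway never splits into persistent branches")
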