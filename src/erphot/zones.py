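"""Region-of-interest detection, radial symmetry point and zone illuminance.

The photometric image of an ellipsoidal-reflector photometer is analyzed
in three concentric zones around the spot's radial symmetry point: the
central circle A1 (radius R1, roughly the collimated beam), the middle
ring A2 (R1–R2) and the external ring A3 (R2–R3). Zone illuminance is the
sum of pixel digital numbers in the zone divided by the zone's pixel count
— a per-ring brightness statistic, not a radiometric lux value.

Zone membership uses the pixel-center distance with half-open intervals
(R_inner <= dist < R_outer), so the three zones partition the R3 disk
exactly; boundary pixels are never counted twice and never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frames import PhotometricFrame
from .synth import OcclusionSpec

DEFAULT_TAU0 = 0.5
DEFAULT_TAU_STEP = 0.05
DEFAULT_TAU_MIN = 0.05
DEFAULT_FORM_LIMITS = (0.8, 1.25)


class RoiNotFoundError(ValueError):
    """No sensitivity threshold yielded an acceptably square bright area."""

    def __init__(self, message: str, form_value: float | None = None):
        super().__init__(message)
        self.form_value = form_value


@dataclass
class RegionOfInterest:
    """Square bounding the bright area, half-open pixel bounds.

    ``threshold_used`` is the sensitivity threshold (fraction of the
    frame's maximum DN) at which the bright area passed the form test;
    ``form_value`` is the side ratio (rows/cols) of the raw thresholded
    bounding box before square expansion.
    """

    row0: int
    col0: int
    row1: int
    col1: int
    threshold_used: float
    form_value: float

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI bounds must be non-empty half-open intervals")

    @property
    def side(self) -> int:
        return max(self.row1 - self.row0, self.col1 - self.col0)


@dataclass
class SymmetryPoint:
    """Radial symmetry point in continuous pixel coordinates.

    For an odd ROI side the point is the center of the central pixel; for
    an even side it is the common corner of the four central pixels. Both
    cases coincide with the midpoint of the half-open ROI bounds.
    """

    rc: tuple[float, float]
    parity: str  # "odd" | "even"


def detect_roi(
    frame: PhotometricFrame,
    tau0: float = DEFAULT_TAU0,
    tau_step: float = DEFAULT_TAU_STEP,
    tau_min: float = DEFAULT_TAU_MIN,
    form_limits: tuple[float, float] = DEFAULT_FORM_LIMITS,
) -> RegionOfInterest:
    """Find the square region of interest by thresholded line scanning.

    Pixels at or above ``tau * max(frame)`` are taken as bright; the rows
    and columns containing any bright pixel give a bounding box whose side
    ratio (rows/cols) is the form objective. Starting from ``tau0``, the
    sensitivity threshold is lowered by ``tau_step`` until the form value
    falls within ``form_limits`` (or ``tau_min`` is passed, which raises
    :class:`RoiNotFoundError` reporting the last form value). The accepted
    box is expanded to a square about its own center, clipped to the frame.
    """
    if not (0 < tau_min <= tau0 <= 1):
        raise ValueError("need 0 < tau_min <= tau0 <= 1")
    lo, hi = form_limits
    if not (lo <= 1 <= hi):
        raise ValueError("form_limits must bracket 1")
    peak = frame.pixels.max()
    if peak <= 0:
        raise RoiNotFoundError("no bright area: frame is all zeros")

    form_value = None
    tau = tau0
    while tau >= tau_min - 1e-12:
        bright = frame.pixels >= tau * peak
        rows = np.flatnonzero(bright.any(axis=1))
        cols = np.flatnonzero(bright.any(axis=0))
        if rows.size and cols.size:
            r0, r1 = int(rows[0]), int(rows[-1]) + 1
            c0, c1 = int(cols[0]), int(cols[-1]) + 1
            form_value = (r1 - r0) / (c1 - c0)
            if lo <= form_value <= hi:
                r0, c0, r1, c1 = _expand_to_square(
                    r0, c0, r1, c1, frame.shape
                )
                return RegionOfInterest(r0, c0, r1, c1, tau, form_value)
        tau -= tau_step
    raise RoiNotFoundError(
        f"no threshold in [{tau_min}, {tau0}] gives a bright area with form "
        f"value in {form_limits} (last form value: {form_value})",
        form_value=form_value,
    )


def _expand_to_square(
    r0: int, c0: int, r1: int, c1: int, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """Grow the shorter box dimension symmetrically; clip to the frame."""
    height, width = r1 - r0, c1 - c0
    side = max(height, width)
    pad_r, pad_c = side - height, side - width
    r0 -= pad_r // 2
    r1 += pad_r - pad_r // 2
    c0 -= pad_c // 2
    c1 += pad_c - pad_c // 2
    return (
        max(r0, 0),
        max(c0, 0),
        min(r1, shape[0]),
        min(c1, shape[1]),
    )


def symmetry_point(roi: RegionOfInterest) -> SymmetryPoint:
    """Radial symmetry point of a (square) ROI.

    An odd side selects the central pixel, whose center — under the
    (row + 0.5, col + 0.5) pixel-center convention — is the midpoint of
    the half-open bounds; an even side selects the shared corner of the
    four central pixels, which is the same midpoint. ``parity`` records
    which case applied (by the row side).
    """
    rc = ((roi.row0 + roi.row1) / 2.0, (roi.col0 + roi.col1) / 2.0)
    parity = "odd" if (roi.row1 - roi.row0) % 2 else "even"
    return SymmetryPoint(rc=rc, parity=parity)


@dataclass
class ZoneGeometry:
    """Symmetry point plus the three zone radii (pixels)."""

    center: SymmetryPoint
    R1_px: float
    R2_px: float
    R3_px: float

    def __post_init__(self) -> None:
        if not 0 < self.R1_px < self.R2_px < self.R3_px:
            raise ValueError("radii must satisfy 0 < R1 < R2 < R3")


@dataclass
class ZoneIlluminance:
    """Per-zone illuminances (zone-mean DN) for one frame."""

    E_A1: float
    E_A2: float
    E_A3: float
    area_A1: int
    area_A2: int
    area_A3: int
    thickness_mm: float
    power_mW: float
    mode: str
    site_index: int
    capture_index: int


def zone_masks(
    geom: ZoneGeometry, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks of A1 (disk), A2 and A3 (rings), mutually exclusive.

    Pixel p belongs to A1 iff dist(center, p_center) < R1, to A2 iff
    R1 <= dist < R2, to A3 iff R2 <= dist < R3. Raises if the R3 circle
    does not fit inside the frame.
    """
    r0, c0 = geom.center.rc
    if (
        r0 - geom.R3_px < 0
        or c0 - geom.R3_px < 0
        or r0 + geom.R3_px > shape[0]
        or c0 + geom.R3_px > shape[1]
    ):
        raise ValueError("R3 circle exceeds frame bounds")
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    dist = np.hypot(rows - r0, cols - c0)
    a1 = dist < geom.R1_px
    a2 = (dist >= geom.R1_px) & (dist < geom.R2_px)
    a3 = (dist >= geom.R2_px) & (dist < geom.R3_px)
    return a1, a2, a3


def zone_illuminance(
    frame: PhotometricFrame,
    geom: ZoneGeometry,
    exclude: OcclusionSpec | None = None,
) -> ZoneIlluminance:
    """Zone illuminance: summed DN over included zone pixels / their count.

    ``exclude`` removes occluded pixels from both sum and area (off by
    default: a systematic central shadow biases all frames of a batch
    equally and is normally left in). Raises if exclusion empties a zone.
    """
    masks = zone_masks(geom, frame.shape)
    if exclude is not None:
        keep = ~exclude.mask(frame.shape)
        masks = tuple(m & keep for m in masks)
    values = []
    areas = []
    for name, mask in zip(("A1", "A2", "A3"), masks):
        area = int(mask.sum())
        if area == 0:
            raise ValueError(f"zone {name} has no included pixels")
        values.append(float(frame.pixels[mask].sum()) / area)
        areas.append(area)
    return ZoneIlluminance(
        E_A1=values[0],
        E_A2=values[1],
        E_A3=values[2],
        area_A1=areas[0],
        area_A2=areas[1],
        area_A3=areas[2],
        thickness_mm=frame.thickness_mm,
        power_mW=frame.power_mW,
        mode=frame.mode,
        site_index=frame.site_index,
        capture_index=frame.capture_index,
    )


def illuminance_table(measurements: Iterable[ZoneIlluminance]) -> pd.DataFrame:
    """One row per frame: metadata, E_A1..E_A3 and zone areas."""
    rows = [vars(m) for m in measurements]
    if not rows:
        raise ValueError("no measurements")
    return pd.DataFrame(rows)


def average_replicates(
    measurements: Iterable[ZoneIlluminance] | pd.DataFrame,
) -> pd.DataFrame:
    """Average zone illuminances over sites x captures per condition.

    Groups by (thickness_mm, power_mW, mode) and takes the arithmetic mean
    of E_A1, E_A2 and E_A3; ``n_replicates`` counts the frames averaged.
    """
    table = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else illuminance_table(measurements)
    )
    if table.empty:
        raise ValueError("cannot average an empty measurement table")
    grouped = (
        table.groupby(["thickness_mm", "power_mW", "mode"], as_index=False)
        .agg(
            E_A1=("E_A1", "mean"),
            E_A2=("E_A2", "mean"),
            E_A3=("E_A3", "mean"),
            n_replicates=("E_A2", "size"),
        )
        .sort_values(["mode", "power_mW", "thickness_mm"], ignore_index=True)
    )
    return grouped
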