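"""Synthetic photometric-frame generator.

Emulates the images an ellipsoidal-reflector photometer forms on its CCD:
a bright central circle (radius ~ the collimated-beam radius), a middle
ring and an external ring whose mean brightness follows the two-stage
illuminance model (exponential in thickness for transmitted light,
logarithmic for reflected light, coefficients polynomial in laser power),
plus Gaussian read noise, optional darkened occlusion rectangles (the
shadow of the delivery prism and tube seen by the reflected-light camera)
and integer quantization.

The within-zone profile is flat: the analysis consumes only zone means, so
finer radial structure would add nothing the pipeline could detect.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference
from .fitting import FAMILIES, PowerPolynomial
from .frames import MANIFEST_COLUMNS, FrameSet, PhotometricFrame, write_frame, write_manifest

# Default geometry: a 640x480 sensor imaging a field whose radius is the
# reflector's focal parameter (16.7 mm) across the short axis gives about
# 14.4 px/mm; the collimated beam is 2 mm in diameter.
DEFAULT_SHAPE = (480, 640)
DEFAULT_PX_PER_MM = 14.4
DEFAULT_R1_PX = 14.4
DEFAULT_R2_PX = 72.0
DEFAULT_R3_PX = 144.0
DEFAULT_LEVEL_A1 = 30000.0  # DN; the central circle is the brightest zone
DEFAULT_BACKGROUND = 10.0  # DN
DEFAULT_NOISE_SD = 2.0  # DN, Gaussian read noise
DEFAULT_GAIN = 1.0  # DN per model illuminance unit

#: replicate protocol: three measurement points on the sample perimeter,
#: three captures each, averaged downstream
DEFAULT_REPLICATES = (3, 3)


@dataclass
class OcclusionSpec:
    """Darkened axis-aligned rectangles (prism/tube shadow), multiplicative.

    ``rectangles`` are half-open pixel boxes (row0, col0, row1, col1);
    ``attenuation`` multiplies the noiseless signal inside them.
    """

    rectangles: list[tuple[int, int, int, int]]
    attenuation: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        for box in self.rectangles:
            r0, c0, r1, c1 = box
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"degenerate occlusion box {box}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for r0, c0, r1, c1 in self.rectangles:
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
                raise ValueError(
                    f"occlusion box {(r0, c0, r1, c1)} exceeds frame shape {shape}"
                )
            out[r0:r1, c0:c1] = True
        return out


@dataclass
class SpotModel:
    """Geometry and target levels of one synthetic scattering spot."""

    center_rc: tuple[float, float]
    R1_px: float = DEFAULT_R1_PX
    R2_px: float = DEFAULT_R2_PX
    R3_px: float = DEFAULT_R3_PX
    level_A1: float = DEFAULT_LEVEL_A1
    level_A2: float = 0.0
    level_A3: float = 0.0
    background: float = DEFAULT_BACKGROUND
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.R1_px < self.R2_px < self.R3_px:
            raise ValueError("radii must satisfy 0 < R1 < R2 < R3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("level_A1", "level_A2", "level_A3", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ForwardModel:
    """The fitted illuminance model used to drive the generator.

    ``polys`` maps (family, ring) — family in m/n (transmitted) and a/b
    (reflected), ring in A2/A3 — to its power polynomial. ``gain`` converts
    model illuminance units to DN when rendering frames.
    """

    polys: dict[tuple[str, str], PowerPolynomial]
    gain: float = DEFAULT_GAIN

    def __post_init__(self) -> None:
        for (name, ring), poly in self.polys.items():
            expected = FAMILIES[name][1]
            if poly.degree != expected:
                raise ValueError(
                    f"{name}({ring}) must have degree {expected}, got {poly.degree}"
                )

    @classmethod
    def from_reference(cls, gain: float = DEFAULT_GAIN) -> "ForwardModel":
        """Forward model with the published polyethylene-film coefficients."""
        return cls(
            polys={(p.name, p.ring): p for p in reference.reference_polynomials()},
            gain=gain,
        )


def model_illuminance(fm: ForwardModel, ring: str, mode: str, d, P):
    """Evaluate the illuminance model in model units (gain not applied).

    transmitted: m(P) * exp(n(P) * d); reflected: a(P) * ln(d) + b(P),
    natural logarithm. Vectorized over ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("thickness d must be positive")
    if np.any(np.asarray(P, dtype=float) <= 0):
        raise ValueError("laser power P must be positive")
    if mode == "transmitted":
        m = fm.polys[("m", ring)](P)
        n = fm.polys[("n", ring)](P)
        out = m * np.exp(n * d)
    elif mode == "reflected":
        a = fm.polys[("a", ring)](P)
        b = fm.polys[("b", ring)](P)
        out = a * np.log(d) + b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


def _zone_index(shape: tuple[int, int], model: SpotModel) -> np.ndarray:
    """0=A1, 1=A2, 2=A3, 3=background, by pixel-center distance, half-open."""
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    r0, c0 = model.center_rc
    dist = np.hypot(rows - r0, cols - c0)
    out = np.full(shape, 3, dtype=np.int8)
    out[dist < model.R3_px] = 2
    out[dist < model.R2_px] = 1
    out[dist < model.R1_px] = 0
    return out


def render_frame(
    model: SpotModel,
    occ: OcclusionSpec | None = None,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    bit_depth: int = 16,
    *,
    thickness_mm: float = 1.0,
    power_mW: float = 1.0,
    mode: str = "transmitted",
    site_index: int = 1,
    capture_index: int = 1,
) -> PhotometricFrame:
    """Render one synthetic frame.

    Each pixel takes its zone's level (A1 disk, A2/A3 rings, background) by
    the same half-open pixel-center distance rule the zone analysis uses,
    occlusion rectangles attenuate the signal multiplicatively, Gaussian
    read noise (seeded from ``model.seed``) is added, and the result is
    clipped to the sensor range and rounded to integer DN.
    """
    r0, c0 = model.center_rc
    if (
        r0 - model.R3_px < 0
        or c0 - model.R3_px < 0
        or r0 + model.R3_px > shape[0]
        or c0 + model.R3_px > shape[1]
    ):
        raise ValueError("outer zone R3 does not fit inside the frame")
    levels = np.array(
        [model.level_A1, model.level_A2, model.level_A3, model.background]
    )
    signal = levels[_zone_index(shape, model)]
    if occ is not None:
        signal = np.where(occ.mask(shape), signal * occ.attenuation, signal)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        signal = signal + rng.normal(0.0, model.noise_sd, size=shape)
    limit = 2**bit_depth - 1
    pixels = np.rint(np.clip(signal, 0, limit))
    return PhotometricFrame(
        pixels=pixels,
        bit_depth=bit_depth,
        thickness_mm=thickness_mm,
        power_mW=power_mW,
        mode=mode,
        site_index=site_index,
        capture_index=capture_index,
    )


def default_occlusion(
    center_rc: tuple[float, float], R1_px: float = DEFAULT_R1_PX
) -> OcclusionSpec:
    """Prism/tube shadow: one rectangle inscribed in the central circle."""
    half = R1_px / np.sqrt(2.0)
    r0, c0 = center_rc
    return OcclusionSpec(
        rectangles=[
            (
                int(round(r0 - half)),
                int(round(c0 - half)),
                int(round(r0 + half)),
                int(round(c0 + half)),
            )
        ],
        attenuation=0.2,
    )


def _frame_seed(seed: int, *key) -> int:
    """Stable per-frame sub-seed from the study seed and the frame key."""
    digest = hashlib.sha256(repr((seed, *key)).encode()).digest()
    return int.from_bytes(digest[:4], "big")


def generate_study(
    fm: ForwardModel,
    thickness_grid: Sequence[float],
    power_grid: Sequence[float],
    replicates: tuple[int, int] = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    bit_depth: int = 16,
    *,
    modes: Sequence[str] = ("transmitted", "reflected"),
    center_rc: tuple[float, float] | None = None,
    R1_px: float = DEFAULT_R1_PX,
    R2_px: float = DEFAULT_R2_PX,
    R3_px: float = DEFAULT_R3_PX,
    level_A1: float = DEFAULT_LEVEL_A1,
    background: float = DEFAULT_BACKGROUND,
    occlude_reflected: bool = True,
    out_dir: str | Path | None = None,
) -> tuple[FrameSet, pd.DataFrame]:
    """Generate one frame per (thickness, power, mode, site, capture).

    Ring target levels are ``gain * model_illuminance`` (clipped at zero:
    the sensor cannot record negative light, which the logarithmic
    reflected model can predict at sub-millimetre thicknesses). Reflected
    frames carry the default central occlusion rectangle. Deterministic
    under a fixed ``seed``. If ``out_dir`` is given, images and a manifest
    CSV (``manifest.csv``) compatible with :func:`erphot.frames.load_frameset`
    are written there.
    """
    thickness_grid = [float(t) for t in thickness_grid]
    power_grid = [float(p) for p in power_grid]
    if not thickness_grid or not power_grid:
        raise ValueError("thickness and power grids must be non-empty")
    if min(thickness_grid) <= 0 or min(power_grid) <= 0:
        raise ValueError("grids must be strictly positive")
    n_sites, n_captures = replicates
    if center_rc is None:
        center_rc = (shape[0] / 2.0, shape[1] / 2.0)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    frames: list[PhotometricFrame] = []
    manifest_rows: list[dict] = []
    occ_cache = default_occlusion(center_rc, R1_px)
    for mode in modes:
        for d in thickness_grid:
            for P in power_grid:
                lvl = {
                    ring: max(0.0, fm.gain * model_illuminance(fm, ring, mode, d, P))
                    for ring in ("A2", "A3")
                }
                for site in range(1, n_sites + 1):
                    for cap in range(1, n_captures + 1):
                        spot = SpotModel(
                            center_rc=center_rc,
                            R1_px=R1_px,
                            R2_px=R2_px,
                            R3_px=R3_px,
                            level_A1=level_A1,
                            level_A2=lvl["A2"],
                            level_A3=lvl["A3"],
                            background=background,
                            noise_sd=noise_sd,
                            seed=_frame_seed(seed, mode, d, P, site, cap),
                        )
                        occ = occ_cache if (mode == "reflected" and occlude_reflected) else None
                        frame = render_frame(
                            spot,
                            occ,
                            shape,
                            bit_depth,
                            thickness_mm=d,
                            power_mW=P,
                            mode=mode,
                            site_index=site,
                            capture_index=cap,
                        )
                        frames.append(frame)
                        fname = (
                            f"{mode}_d{d:g}_P{P:g}_s{site}_c{cap}.png"
                        )
                        manifest_rows.append(
                            {
                                "path": fname,
                                "thickness_mm": d,
                                "power_mW": P,
                                "mode": mode,
                                "site_index": site,
                                "capture_index": cap,
                            }
                        )
                        if out_path is not None:
                            write_frame(frame, out_path / fname)

    manifest = pd.DataFrame(manifest_rows, columns=list(MANIFEST_COLUMNS))
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return FrameSet(frames, provenance=f"synthetic study seed={seed}"), manifest


def synthesize_illuminance_table(
    fm: ForwardModel,
    thickness_grid_transmitted: Sequence[float],
    thickness_grid_reflected: Sequence[float],
    power_grid: Sequence[float],
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    modes: Sequence[str] = ("transmitted", "reflected"),
) -> pd.DataFrame:
    """Model-level study: illuminances straight from the forward model.

    Bypasses image rendering and zone extraction — each row holds the
    model's ring illuminances (model units, gain not applied) for one
    (thickness, power, mode), optionally perturbed by Gaussian noise.
    This is the fast path for regression self-consistency checks where
    pixel quantization is not under study.
    """
    rng = np.random.default_rng(seed)
    grids = {
        "transmitted": [float(t) for t in thickness_grid_transmitted],
        "reflected": [float(t) for t in thickness_grid_reflected],
    }
    rows = []
    for mode in modes:
        for d in grids[mode]:
            for P in power_grid:
                row = {"thickness_mm": d, "power_mW": float(P), "mode": mode}
                for ring in ("A2", "A3"):
                    value = model_illuminance(fm, ring, mode, d, P)
                    if noise_sd > 0:
                        value += rng.normal(0.0, noise_sd)
                    row[f"E_{ring}"] = value
                rows.append(row)
    return pd.DataFrame(rows)
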