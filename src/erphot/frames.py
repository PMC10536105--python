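"""Grayscale photometric frames and their acquisition metadata.

A photometric frame is one CCD capture of the scattering spot projected by
an ellipsoidal reflector, together with the acquisition conditions that the
downstream regression needs: sample thickness, laser power, light mode
(transmitted or reflected) and the replicate indices (measurement site on
the sample perimeter, capture number at that site).

Pixels are held as float64 digital numbers (DN) internally so that zone
statistics are never truncated; files on disk remain integer (8- or 16-bit
grayscale PNG, TIFF or binary PGM).

Coordinate convention: pixel (row, col), 0-based, row 0 at top; the center
of pixel (r, c) is the continuous point (r + 0.5, c + 0.5). All radii used
by the zone analysis are distances from the symmetry point in pixel units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

MODES = ("transmitted", "reflected")

#: columns a frame-set manifest must provide, in canonical order
MANIFEST_COLUMNS = (
    "path",
    "thickness_mm",
    "power_mW",
    "mode",
    "site_index",
    "capture_index",
)


@dataclass
class PhotometricFrame:
    """One grayscale capture plus its acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D float array of non-negative digital numbers.
    bit_depth:
        8 or 16; bounds the admissible pixel range [0, 2**bit_depth - 1].
    thickness_mm:
        Thickness of the light-scattering sample, mm (> 0).
    power_mW:
        Laser power of the collimated beam, mW (> 0).
    mode:
        ``"transmitted"`` (forward-scattered light) or ``"reflected"``
        (backscattered light).
    site_index, capture_index:
        1-based replicate indices: measurement point on the sample
        perimeter and capture number at that point.
    """

    pixels: np.ndarray
    bit_depth: int
    thickness_mm: float
    power_mW: float
    mode: str
    site_index: int = 1
    capture_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        limit = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > limit:
            raise ValueError(f"pixel values must lie in [0, {limit}]")
        if not self.thickness_mm > 0:
            raise ValueError("thickness_mm must be positive")
        if not self.power_mW > 0:
            raise ValueError("power_mW must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.site_index < 1 or self.capture_index < 1:
            raise ValueError("site_index and capture_index are 1-based")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_dn(self) -> int:
        return 2**self.bit_depth - 1

    def metadata_key(self) -> tuple:
        """Key identifying one acquisition within a study."""
        return (
            self.thickness_mm,
            self.power_mW,
            self.mode,
            self.site_index,
            self.capture_index,
        )


@dataclass
class FrameSet:
    """Ordered, shape- and depth-homogeneous collection of frames."""

    frames: list[PhotometricFrame]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.frames:
            shape = self.frames[0].shape
            depth = self.frames[0].bit_depth
            for i, f in enumerate(self.frames):
                if f.shape != shape:
                    raise ValueError(
                        f"frame {i} has shape {f.shape}, expected {shape}"
                    )
                if f.bit_depth != depth:
                    raise ValueError(
                        f"frame {i} has bit depth {f.bit_depth}, expected {depth}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[PhotometricFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> PhotometricFrame:
        return self.frames[i]


def _dtype_for_depth(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth == 8 else np.uint16)


def read_frame(path: str | os.PathLike, sidecar: Mapping) -> PhotometricFrame:
    """Read a grayscale image file and attach sidecar metadata.

    ``sidecar`` must supply ``thickness_mm``, ``power_mW`` and ``mode``;
    ``site_index`` and ``capture_index`` default to 1. Color or
    multichannel images are rejected: the photometer CCDs are monochrome
    and a silent channel collapse would corrupt DN statistics.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel grayscale image, got shape {raw.shape}"
        )
    if raw.max(initial=0) > 255 or np.dtype(raw.dtype).itemsize > 1:
        bit_depth = 16
    else:
        bit_depth = 8
    return PhotometricFrame(
        pixels=raw.astype(np.float64),
        bit_depth=bit_depth,
        thickness_mm=float(sidecar["thickness_mm"]),
        power_mW=float(sidecar["power_mW"]),
        mode=str(sidecar["mode"]),
        site_index=int(sidecar.get("site_index", 1)),
        capture_index=int(sidecar.get("capture_index", 1)),
    )


def write_frame(frame: PhotometricFrame, path: str | os.PathLike) -> None:
    """Write a frame's pixels to a grayscale image file (lossless).

    The float DN grid is rounded to the nearest integer of the frame's
    declared bit depth. Supported extensions: .png, .tif/.tiff, .pgm.
    """
    path = Path(path)
    data = np.rint(frame.pixels).astype(_dtype_for_depth(frame.bit_depth))
    iio.imwrite(path, data)


def load_frameset(
    manifest: str | os.PathLike,
    root: str | os.PathLike | None = None,
    provenance: str | None = None,
) -> FrameSet:
    """Load every frame referenced by a CSV manifest, in manifest order.

    The manifest needs the columns of :data:`MANIFEST_COLUMNS`; image paths
    are resolved relative to ``root`` (default: the manifest's directory).
    Duplicate (thickness, power, mode, site, capture) keys and heterogeneous
    image shapes/bit depths are rejected.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest {manifest} lacks columns {missing}")
    base = Path(root) if root is not None else manifest.parent

    frames: list[PhotometricFrame] = []
    seen: dict[tuple, int] = {}
    for i, row in table.iterrows():
        img_path = base / str(row["path"])
        if not img_path.is_file():
            raise FileNotFoundError(
                f"manifest row {i}: image file not found: {img_path}"
            )
        frame = read_frame(img_path, row)
        key = frame.metadata_key()
        if key in seen:
            raise ValueError(
                f"manifest rows {seen[key]} and {i} share the metadata key {key}"
            )
        seen[key] = i
        frames.append(frame)
    return FrameSet(frames, provenance=provenance or str(manifest))


def write_manifest(
    rows: Sequence[Mapping], path: str | os.PathLike
) -> pd.DataFrame:
    """Write a frame-set manifest CSV and return it as a DataFrame."""
    table = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    table.to_csv(path, index=False)
    return table
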