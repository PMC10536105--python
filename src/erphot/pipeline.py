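"""Orchestration: generate -> analyze -> average -> fit, reproducibly.

A :class:`RunConfig` captures every knob of a run (generator grids and
noise, zone geometry and ROI thresholds, regression settings). The
pipeline writes all intermediate tables to the output directory, each
prefixed with a comment line carrying the config hash, plus a
``summary.json`` echoing the full config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import synth, zones
from .fitting import (
    PowerPolynomial,
    power_polynomials_frame,
    run_regression,
    thickness_fits_frame,
)
from .frames import FrameSet, load_frameset
from .reference import POWER_GRID_MW, reference_polynomials
from .synth import ForwardModel, default_occlusion, generate_study, synthesize_illuminance_table
from .zones import ZoneGeometry, average_replicates, detect_roi, illuminance_table, symmetry_point, zone_illuminance

logger = logging.getLogger("erphot")


def _grid(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step))
    return [round(start + k * step, 6) for k in range(n + 1)]


@dataclass
class ZoneSettings:
    """Ring radii and ROI-detection thresholds applied to every frame."""

    R1_px: float = synth.DEFAULT_R1_PX
    R2_px: float = synth.DEFAULT_R2_PX
    R3_px: float = synth.DEFAULT_R3_PX
    tau0: float = zones.DEFAULT_TAU0
    tau_step: float = zones.DEFAULT_TAU_STEP
    tau_min: float = zones.DEFAULT_TAU_MIN
    form_limits: tuple[float, float] = zones.DEFAULT_FORM_LIMITS
    exclude_occlusion: bool = False


@dataclass
class RegressionSettings:
    d_min_mm: float = 0.7
    degrees: dict = field(default_factory=dict)  # override per family if needed


@dataclass
class GeneratorSettings:
    """Synthetic-study conditions; defaults mirror the original experiment.

    Ten laser powers 1.8–23.4 mW (2.4 mW steps); thickness from 0.1 mm
    film stacking up to 10 mm, restricted to > 0.7 mm for transmitted
    light where the exponential model applies; three sites x three
    captures. ``render_images=False`` takes the model-level path
    (illuminances straight from the forward model, no pixel rendering).
    """

    gain: float = synth.DEFAULT_GAIN
    thickness_grid_transmitted: list[float] = field(
        default_factory=lambda: _grid(0.8, 10.0, 0.2)
    )
    thickness_grid_reflected: list[float] = field(
        default_factory=lambda: _grid(0.1, 10.0, 0.1)
    )
    power_grid: list[float] = field(default_factory=lambda: list(POWER_GRID_MW))
    replicates: tuple[int, int] = synth.DEFAULT_REPLICATES
    noise_sd: float = 0.0
    seed: int = 0
    shape: tuple[int, int] = synth.DEFAULT_SHAPE
    bit_depth: int = 16
    render_images: bool = False
    level_A1: float = synth.DEFAULT_LEVEL_A1
    background: float = synth.DEFAULT_BACKGROUND
    occlude_reflected: bool = True


@dataclass
class RunConfig:
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    zones: ZoneSettings = field(default_factory=ZoneSettings)
    regression: RegressionSettings = field(default_factory=RegressionSettings)
    manifest: str | None = None  # path to a real-data manifest; skips generation
    out_dir: str = "erphot_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, data):
            if data is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = dict(data)
            for key in ("replicates", "shape", "form_limits"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(kwargs[key])
            return klass(**kwargs)

        return cls(
            generator=build(GeneratorSettings, raw.get("generator")),
            zones=build(ZoneSettings, raw.get("zones")),
            regression=build(RegressionSettings, raw.get("regression")),
            manifest=raw.get("manifest"),
            out_dir=raw.get("out_dir", "erphot_run"),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_table(table: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, index=False)


def analyze_frameset(
    frames: FrameSet,
    settings: ZoneSettings,
    *,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Per-frame ROI detection, symmetry point and zone illuminances.

    ``on_error="skip"`` logs frames whose ROI search fails and continues;
    ``"raise"`` aborts on the first failure. Returns one row per analyzed
    frame including geometry and threshold diagnostics.
    """
    rows = []
    for i, frame in enumerate(frames):
        try:
            roi = detect_roi(
                frame,
                tau0=settings.tau0,
                tau_step=settings.tau_step,
                tau_min=settings.tau_min,
                form_limits=settings.form_limits,
            )
            center = symmetry_point(roi)
            geom = ZoneGeometry(
                center=center,
                R1_px=settings.R1_px,
                R2_px=settings.R2_px,
                R3_px=settings.R3_px,
            )
            exclude = (
                default_occlusion(center.rc, settings.R1_px)
                if (settings.exclude_occlusion and frame.mode == "reflected")
                else None
            )
            zi = zone_illuminance(frame, geom, exclude)
        except ValueError as exc:
            if on_error == "skip":
                logger.warning("frame %d (%s): %s", i, frame.metadata_key(), exc)
                continue
            raise ValueError(f"zone analysis failed on frame {i}: {exc}") from exc
        row = vars(zi).copy()
        row.update(
            center_row=center.rc[0],
            center_col=center.rc[1],
            parity=center.parity,
            roi_threshold=roi.threshold_used,
            roi_form_value=roi.form_value,
        )
        rows.append(row)
    if not rows:
        raise ValueError("no frame could be analyzed")
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and write result tables.

    Stages: synthetic generation (or real-manifest ingestion), zone
    analysis, replicate averaging, two-stage regression. Returns a bundle
    with the averaged table, stage-1 fits, power polynomials and the paths
    of everything written.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    gen = config.generator
    fm = ForwardModel.from_reference(gain=gen.gain)

    if config.manifest is not None:
        frames = load_frameset(config.manifest)
        per_frame = analyze_frameset(frames, config.zones, on_error="skip")
        averaged = average_replicates(per_frame)
    elif gen.render_images:
        frames, manifest = generate_study(
            fm,
            sorted(
                set(gen.thickness_grid_transmitted) | set(gen.thickness_grid_reflected)
            ),
            gen.power_grid,
            replicates=gen.replicates,
            noise_sd=gen.noise_sd,
            seed=gen.seed,
            shape=gen.shape,
            bit_depth=gen.bit_depth,
            R1_px=config.zones.R1_px,
            R2_px=config.zones.R2_px,
            R3_px=config.zones.R3_px,
            level_A1=gen.level_A1,
            background=gen.background,
            occlude_reflected=gen.occlude_reflected,
        )
        per_frame = analyze_frameset(frames, config.zones, on_error="skip")
        # gain maps model illuminance to DN at render time; divide it back
        # out so the regression reports model-unit coefficients
        for col in ("E_A1", "E_A2", "E_A3"):
            per_frame[col] = per_frame[col] / gen.gain
        per_frame = per_frame[
            (per_frame["mode"] == "reflected")
            | per_frame["thickness_mm"].isin(gen.thickness_grid_transmitted)
        ]
        per_frame = per_frame[
            (per_frame["mode"] == "transmitted")
            | per_frame["thickness_mm"].isin(gen.thickness_grid_reflected)
        ]
        averaged = average_replicates(per_frame)
    else:
        per_frame = None
        averaged = synthesize_illuminance_table(
            fm,
            gen.thickness_grid_transmitted,
            gen.thickness_grid_reflected,
            gen.power_grid,
            noise_sd=gen.noise_sd,
            seed=gen.seed,
        )

    fits, polys = run_regression(
        averaged,
        d_min=config.regression.d_min_mm,
        degrees=config.regression.degrees or None,
    )

    paths = {}
    if per_frame is not None:
        paths["illuminance"] = out / "illuminance.csv"
        _write_table(per_frame, paths["illuminance"], chash)
    paths["averaged"] = out / "averaged.csv"
    _write_table(averaged, paths["averaged"], chash)
    paths["thickness_fits"] = out / "thickness_fits.csv"
    _write_table(thickness_fits_frame(fits), paths["thickness_fits"], chash)
    paths["power_polynomials"] = out / "power_polynomials.csv"
    _write_table(power_polynomials_frame(polys), paths["power_polynomials"], chash)

    summary = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": gen.seed,
        "n_conditions": int(len(averaged)),
        "n_thickness_fits": len(fits),
        "n_power_polynomials": len(polys),
    }
    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    return {
        "averaged": averaged,
        "per_frame": per_frame,
        "thickness_fits": fits,
        "power_polynomials": polys,
        "paths": paths,
        "config_hash": chash,
    }


def compare_to_reference(
    fitted: Sequence[PowerPolynomial],
    ref: Sequence[PowerPolynomial] | None = None,
    *,
    rtol: float = 1e-3,
    atol: float = 1e-9,
) -> tuple[pd.DataFrame, bool]:
    """Coefficient-wise comparison of fitted polynomials against a reference.

    Each coefficient passes if its relative difference is within ``rtol``
    or its absolute difference within ``atol`` (the absolute escape covers
    near-zero high-order terms where relative error is ill-conditioned).
    Returns the per-coefficient report and the overall verdict. Raises on
    (name, ring) key mismatch.
    """
    if ref is None:
        ref = reference_polynomials()
    fitted_by_key = {(p.name, p.ring): p for p in fitted}
    ref_by_key = {(p.name, p.ring): p for p in ref}
    if set(fitted_by_key) != set(ref_by_key):
        raise ValueError(
            f"key mismatch: fitted {sorted(fitted_by_key)} vs "
            f"reference {sorted(ref_by_key)}"
        )
    rows = []
    for key in sorted(ref_by_key):
        f, r = fitted_by_key[key], ref_by_key[key]
        if f.degree != r.degree:
            raise ValueError(f"degree mismatch for {key}: {f.degree} vs {r.degree}")
        for k, (cf, cr) in enumerate(zip(f.coeffs, r.coeffs)):
            abs_diff = abs(cf - cr)
            rel_diff = abs_diff / abs(cr) if cr != 0 else np.inf
            rows.append(
                {
                    "name": key[0],
                    "ring": key[1],
                    "order": k,
                    "fitted": cf,
                    "reference": cr,
                    "abs_diff": abs_diff,
                    "rel_diff": rel_diff,
                    "pass": bool(abs_diff <= atol or rel_diff <= rtol),
                }
            )
    report = pd.DataFrame(rows)
    return report, bool(report["pass"].all())
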