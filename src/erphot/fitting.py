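"""Two-stage regression of zone illuminance.

Stage 1, per laser power, ring and mode:

* transmitted light: ``E_T(d) = m * exp(n * d)``, fitted by nonlinear least
  squares on the original scale with log-linear starting values, using only
  thicknesses above ``d_min`` (the exponential describes the regime past a
  fraction of a millimetre where single-scattering transients have died out);
* reflected light: ``E_R(d) = a * ln(d) + b``, an ordinary least-squares
  line in ln(d) with a closed-form solution.

Stage 2, per ring: the stage-1 coefficients as polynomials of laser power P
(mW) — m, a and b quadratic, n sextic — reported with their coefficient of
determination ("approximation reliability").

Coefficient ordering everywhere is constant-first: (c0, c1, ..., c_deg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import curve_fit

RINGS = ("A2", "A3")
#: polynomial family -> (light mode it belongs to, degree in laser power)
FAMILIES = {
    "m": ("transmitted", 2),
    "n": ("transmitted", 6),
    "a": ("reflected", 2),
    "b": ("reflected", 2),
}

DEFAULT_D_MIN_MM = 0.7


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot (centered SStot).

    A perfect fit of constant data (SStot = 0, SSres = 0) is reported as
    1.0; an imperfect fit of constant data as -inf.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot


@dataclass
class ThicknessFit:
    """One stage-1 fit: illuminance versus thickness at a single power."""

    ring: str
    mode: str
    power_mW: float
    params: tuple[float, float]  # (m, n) transmitted; (a, b) reflected
    r_squared: float
    n_points: int
    n_excluded: int = 0

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        p0, p1 = self.params
        if self.mode == "transmitted":
            return p0 * np.exp(p1 * d)
        return p0 * np.log(d) + p1


@dataclass
class PowerPolynomial:
    """Polynomial of laser power P (mW), coefficients constant-first."""

    name: str  # m | n | a | b
    ring: str  # A2 | A3
    coeffs: np.ndarray
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 1 or self.coeffs.size < 1:
            raise ValueError("coeffs must be a 1-D array, constant term first")

    @property
    def degree(self) -> int:
        return self.coeffs.size - 1

    def __call__(self, P) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(np.asarray(P, dtype=float), self.coeffs)


def _as_points(d, E) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    E = np.asarray(E, dtype=float)
    if d.shape != E.shape or d.ndim != 1:
        raise ValueError("d and E must be 1-D arrays of equal length")
    return d, E


def fit_transmitted(
    d,
    E,
    *,
    d_min: float = DEFAULT_D_MIN_MM,
    ring: str = "A2",
    power_mW: float = float("nan"),
) -> ThicknessFit:
    """Fit E = m * exp(n * d) to transmitted-light illuminances.

    Points with d <= d_min are excluded before fitting (and counted in
    ``n_excluded``). Starting values come from the exact log-linear
    solution; a Levenberg–Marquardt refinement on the original scale is
    then accepted only if it does not increase the residual sum of squares.
    r² is computed on the original (not log) scale.
    """
    d, E = _as_points(d, E)
    keep = d > d_min
    n_excluded = int((~keep).sum())
    d_use, E_use = d[keep], E[keep]
    if d_use.size < 3:
        raise ValueError(
            f"need at least 3 points with d > {d_min} mm, have {d_use.size}"
        )
    if np.any(E_use <= 0):
        raise ValueError("transmitted illuminances must be positive to fit m*exp(n*d)")

    slope, intercept = np.polyfit(d_use, np.log(E_use), 1)
    m0, n0 = float(np.exp(intercept)), float(slope)
    ss0 = float(np.sum((E_use - m0 * np.exp(n0 * d_use)) ** 2))

    params = (m0, n0)
    ss_best = ss0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, m, n: m * np.exp(n * x), d_use, E_use, p0=[m0, n0]
            )
        ss_ref = float(np.sum((E_use - popt[0] * np.exp(popt[1] * d_use)) ** 2))
        if ss_ref <= ss0:
            params = (float(popt[0]), float(popt[1]))
            ss_best = ss_ref
    except RuntimeError:
        pass  # refinement failed to converge; keep the log-linear solution

    pred = params[0] * np.exp(params[1] * d_use)
    return ThicknessFit(
        ring=ring,
        mode="transmitted",
        power_mW=power_mW,
        params=params,
        r_squared=r_squared(E_use, pred),
        n_points=int(d_use.size),
        n_excluded=n_excluded,
    )


def fit_reflected(
    d, E, *, ring: str = "A2", power_mW: float = float("nan")
) -> ThicknessFit:
    """Fit E = a * ln(d) + b by ordinary least squares (closed form)."""
    d, E = _as_points(d, E)
    if d.size < 3:
        raise ValueError(f"need at least 3 points, have {d.size}")
    if np.any(d <= 0):
        raise ValueError("thickness must be positive (ln d undefined otherwise)")
    x = np.log(d)
    design = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(design, E, rcond=None)
    pred = a * x + b
    return ThicknessFit(
        ring=ring,
        mode="reflected",
        power_mW=power_mW,
        params=(float(a), float(b)),
        r_squared=r_squared(E, pred),
        n_points=int(d.size),
    )


def fit_power_polynomial(
    P, values, degree: int, *, name: str = "", ring: str = ""
) -> PowerPolynomial:
    """Least-squares polynomial of the stated degree in laser power.

    Fitted in a shifted/scaled basis for conditioning (degree 6 over a
    1.8–23.4 mW grid is badly conditioned in the raw monomial basis) and
    converted back to raw constant-first coefficients.
    """
    P = np.asarray(P, dtype=float)
    values = np.asarray(values, dtype=float)
    n_distinct = np.unique(P).size
    if n_distinct < degree + 1:
        raise ValueError(
            f"degree-{degree} fit needs at least {degree + 1} distinct powers, "
            f"have {n_distinct}"
        )
    poly = Polynomial.fit(P, values, degree).convert()
    coeffs = np.zeros(degree + 1)
    coeffs[: poly.coef.size] = poly.coef
    pred = np.polynomial.polynomial.polyval(P, coeffs)
    return PowerPolynomial(
        name=name, ring=ring, coeffs=coeffs, r_squared=r_squared(values, pred)
    )


def run_regression(
    averaged: pd.DataFrame,
    *,
    d_min: float = DEFAULT_D_MIN_MM,
    degrees: dict[str, int] | None = None,
) -> tuple[list[ThicknessFit], list[PowerPolynomial]]:
    """Run both regression stages on an averaged-illuminance table.

    ``averaged`` needs columns thickness_mm, power_mW, mode, E_A2, E_A3
    (one row per (thickness, power, mode) after replicate averaging).
    Stage 1 fits the thickness model per (power, ring, mode); stage 2 fits
    each coefficient family over power where enough power levels exist,
    otherwise skips that family with a warning.
    """
    degrees = {**{k: v[1] for k, v in FAMILIES.items()}, **(degrees or {})}
    required = {"thickness_mm", "power_mW", "mode", "E_A2", "E_A3"}
    missing = required - set(averaged.columns)
    if missing:
        raise ValueError(f"averaged table lacks columns {sorted(missing)}")

    fits: list[ThicknessFit] = []
    for (mode, power), group in averaged.groupby(["mode", "power_mW"]):
        group = group.sort_values("thickness_mm")
        d = group["thickness_mm"].to_numpy()
        for ring in RINGS:
            E = group[f"E_{ring}"].to_numpy()
            try:
                if mode == "transmitted":
                    fit = fit_transmitted(
                        d, E, d_min=d_min, ring=ring, power_mW=float(power)
                    )
                else:
                    fit = fit_reflected(d, E, ring=ring, power_mW=float(power))
            except ValueError as exc:
                raise ValueError(
                    f"stage-1 fit failed for power={power} mW, ring={ring}, "
                    f"mode={mode}: {exc}"
                ) from exc
            fits.append(fit)

    polynomials: list[PowerPolynomial] = []
    for family, (mode, _default_deg) in FAMILIES.items():
        degree = degrees[family]
        param_idx = 0 if family in ("m", "a") else 1
        for ring in RINGS:
            sub = [f for f in fits if f.mode == mode and f.ring == ring]
            if not sub:
                continue  # that mode absent from the input
            sub.sort(key=lambda f: f.power_mW)
            P = np.array([f.power_mW for f in sub])
            vals = np.array([f.params[param_idx] for f in sub])
            if np.unique(P).size < degree + 1:
                warnings.warn(
                    f"skipping {family}(P) for ring {ring}: degree-{degree} fit "
                    f"needs {degree + 1} distinct powers, have {np.unique(P).size}",
                    stacklevel=2,
                )
                continue
            polynomials.append(
                fit_power_polynomial(P, vals, degree, name=family, ring=ring)
            )
    return fits, polynomials


def thickness_fits_frame(fits: list[ThicknessFit]) -> pd.DataFrame:
    """Stage-1 results as a tidy table."""
    rows = []
    for f in fits:
        c0_name, c1_name = ("m", "n") if f.mode == "transmitted" else ("a", "b")
        rows.append(
            {
                "mode": f.mode,
                "ring": f.ring,
                "power_mW": f.power_mW,
                c0_name: f.params[0],
                c1_name: f.params[1],
                "r_squared": f.r_squared,
                "n_points": f.n_points,
                "n_excluded": f.n_excluded,
            }
        )
    return pd.DataFrame(rows)


def power_polynomials_frame(polys: list[PowerPolynomial]) -> pd.DataFrame:
    """Stage-2 results: name, ring, mode, degree, c0..c6, r_squared."""
    max_deg = 6
    rows = []
    for p in polys:
        row: dict = {
            "name": p.name,
            "ring": p.ring,
            "mode": FAMILIES.get(p.name, ("", None))[0],
            "degree": p.degree,
        }
        for k in range(max_deg + 1):
            row[f"c{k}"] = p.coeffs[k] if k <= p.degree else np.nan
        row["r_squared"] = p.r_squared
        rows.append(row)
    return pd.DataFrame(rows)
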