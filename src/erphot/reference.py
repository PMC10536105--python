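"""Published calibration coefficients for the polyethylene-film standard.

These are the fitted power-polynomial coefficients of the two-stage
illuminance model for stacked 0.1 mm polyethylene film measured at 650 nm
on an ellipsoidal-reflector CCD photometer: per ring (middle A2, external
A3), the exponential amplitude m and rate n of the transmitted-light model
E_T(d) = m * exp(n * d), and the slope a and intercept b of the
reflected-light model E_R(d) = a * ln(d) + b, each as a polynomial of laser
power P in mW (m, a, b quadratic; n sextic), coefficients constant-first.

``reliability`` is the published coefficient of determination of each
coefficient-versus-power fit. Illuminance is in the instrument's model
units (zone-mean digital numbers of the calibrated sensor), not lux.
"""

from __future__ import annotations

from .fitting import PowerPolynomial

#: (family, ring) -> (constant-first coefficients, approximation reliability)
TABLE: dict[tuple[str, str], tuple[tuple[float, ...], float]] = {
    ("m", "A2"): ((757.62, 1799.9, -32.413), 0.9993),
    ("m", "A3"): ((-127.22, 1761.9, -25.227), 0.9984),
    ("n", "A2"): (
        (-0.1335, -0.0521, 0.0105, -0.0011, 0.00006, -0.000002, 0.00000002),
        0.9966,
    ),
    ("n", "A3"): (
        (-0.1291, -0.0557, 0.0104, -0.0011, 0.00006, -0.000002, 0.00000002),
        0.9991,
    ),
    ("a", "A2"): ((1397.1, 383.68, -6.9252), 0.9993),
    ("a", "A3"): ((-735.69, 687.74, -13.634), 0.9955),
    ("b", "A2"): ((109.24, 122.66, -2.3069), 0.9983),
    ("b", "A3"): ((-29.994, 240.34, -5.7102), 0.9957),
}

#: power grid of the original study: 1.8–23.4 mW in steps of 2.4 mW
POWER_GRID_MW: tuple[float, ...] = tuple(round(1.8 + 2.4 * k, 1) for k in range(10))


def reference_polynomials() -> list[PowerPolynomial]:
    """The published coefficients as :class:`PowerPolynomial` objects."""
    return [
        PowerPolynomial(name=name, ring=ring, coeffs=list(coeffs), r_squared=rel)
        for (name, ring), (coeffs, rel) in TABLE.items()
    ]


def reference_polynomial(name: str, ring: str) -> PowerPolynomial:
    coeffs, rel = TABLE[(name, ring)]
    return PowerPolynomial(name=name, ring=ring, coeffs=list(coeffs), r_squared=rel)
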