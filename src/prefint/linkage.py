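"""Wyman linkage between solvation and association constants.

Linkage theory states d ln K_A / d ln a_x = delta Gamma: a cosolvent shifts
the binding equilibrium toward the state that interacts with it most
favorably.  When K_A responds exponentially to cosolvent molality (i.e.
ln K_A is linear in m_x, the empirically common case) and the cosolvent
activity is taken proportional to molality, the relation integrates to

    ln(K_A / K_A0) = delta Gamma_exp(m) = s * m,

so the slope of ln(K_A/K_A0) against molality directly measures the change
of the preferential interaction coefficient on association.  K_A values are
estimated from steady-state binding responses by Scatchard analysis:
R/C = K_A * (R_max - R), a line in R with slope -K_A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class ScatchardError(ValueError):
    """Binding data incompatible with a 1:1 Scatchard line."""


@dataclass(frozen=True)
class BindingIsotherm:
    """Steady-state binding responses at one cosolvent molality."""

    concentrations: np.ndarray   # analyte concentration, molar
    responses: np.ndarray        # steady-state response (arbitrary RU)
    molality: float = 0.0        # cosolvent molality of the buffer, mol/kg

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        if len(c) != len(r):
            raise ValueError("concentrations and responses differ in length")
        if len(c) < 3:
            raise ValueError("need at least 3 isotherm points")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be distinct")


@dataclass(frozen=True)
class ScatchardFit:
    ka: float          # association constant, 1/M
    r_max: float       # saturation response
    residual_rms: float
    r_squared: float
    curvature_warning: bool  # set when a quadratic term dominates residuals


def scatchard_ka(isotherm: BindingIsotherm) -> ScatchardFit:
    """Association constant by Scatchard linearization.

    Fits R/C against R; the slope is -K_A and the intercept K_A * R_max.
    Noiseless 1:1 data is inverted exactly.  A curvature warning is raised
    when a quadratic fit reduces the residual spread substantially,
    indicating non-1:1 binding.
    """
    r = isotherm.responses
    c = isotherm.concentrations
    if np.allclose(r, r[0]):
        raise ScatchardError("responses are all equal; no binding signal")
    y = r / c
    slope, intercept = np.polyfit(r, y, 1)
    if slope >= 0:
        raise ScatchardError(
            "non-negative Scatchard slope; data inconsistent with 1:1 binding"
        )
    ka = -float(slope)
    r_max = float(intercept / ka)
    pred = intercept + slope * r
    resid = y - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    curvature = False
    if len(r) >= 4:
        quad = np.polyfit(r, y, 2)
        resid2 = y - np.polyval(quad, r)
        ss2 = float(np.sum(resid2**2))
        curvature = ss_res > 1e-12 and ss2 < 0.25 * ss_res
    return ScatchardFit(
        ka=ka,
        r_max=r_max,
        residual_rms=float(np.sqrt(ss_res / len(r))),
        r_squared=r_squared,
        curvature_warning=curvature,
    )


def nonlinear_ka(isotherm: BindingIsotherm) -> tuple[float, float]:
    """(K_A, R_max) from a direct 1:1 isotherm fit; Scatchard cross-check."""
    start = scatchard_ka(isotherm)

    def model(c, ka, rmax):
        return rmax * ka * c / (1.0 + ka * c)

    popt, _ = curve_fit(
        model,
        isotherm.concentrations,
        isotherm.responses,
        p0=[start.ka, start.r_max],
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


@dataclass(frozen=True)
class LinkageFit:
    """Slope of ln(K_A/K_A0) vs cosolvent molality and what it assumes."""

    slope: float                # kg/mol
    slope_se: float
    ref_molality: float
    ka_ref: float
    assumptions: tuple[str, ...] = (
        "cosolvent activity proportional to molality",
        "delta Gamma linear in molality",
    )

    def delta_gamma(self, molality: float) -> tuple[float, float]:
        """delta Gamma_exp(m) = slope * m with propagated SE; exactly 0 at m=0."""
        return self.slope * molality, self.slope_se * molality


def linkage_fit(
    molalities: np.ndarray,
    ka_values: np.ndarray,
    ka_se: np.ndarray | None = None,
    ref_molality: float = 0.0,
) -> LinkageFit:
    """Weighted least-squares of ln(K_A/K_A0) on molality through the origin.

    The reference K_A0 is the measured value at ``ref_molality`` (not a free
    parameter).  With K_A standard errors the weights are the propagated
    variances of ln K_A (including the shared reference variance, added in
    quadrature); without them the fit is unweighted and the slope SE comes
    from the residuals.
    """
    m = np.asarray(molalities, dtype=float)
    ka = np.asarray(ka_values, dtype=float)
    if len(np.unique(m)) < 2:
        raise ValueError("need at least 2 distinct molalities")
    if np.any(ka <= 0):
        raise ValueError("association constants must be positive")
    ref_idx = np.flatnonzero(np.isclose(m, ref_molality))
    if len(ref_idx) == 0:
        raise ValueError(f"no measurement at the reference molality {ref_molality}")
    i0 = int(ref_idx[0])
    ka0 = ka[i0]
    rest = np.ones(len(m), dtype=bool)
    rest[i0] = False
    x = m[rest] - ref_molality
    y = np.log(ka[rest] / ka0)
    if ka_se is not None:
        se = np.asarray(ka_se, dtype=float)
        var = (se[rest] / ka[rest]) ** 2 + (se[i0] / ka0) ** 2
        w = 1.0 / np.where(var > 0, var, np.min(var[var > 0]) if np.any(var > 0) else 1.0)
    else:
        w = np.ones_like(x)
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y) / sxx)
    if ka_se is not None:
        slope_se = float(np.sqrt(1.0 / sxx))
    else:
        dof = max(len(x) - 1, 1)
        resid = y - slope * x
        slope_se = float(np.sqrt(np.sum(w * resid**2) / dof / sxx))
    return LinkageFit(
        slope=slope, slope_se=slope_se,
        ref_molality=float(ref_molality), ka_ref=float(ka0),
    )


def predicted_ln_ratio(
    delta_gamma_value: float, m_ref: float, molalities: np.ndarray
) -> np.ndarray:
    """Inverse prediction: ln(K_A/K_A0)(m) from a computed delta Gamma at m_ref.

    Under the linear-response assumption the slope is delta_gamma / m_ref, so
    ln(K_A/K_A0)(m) = delta_gamma * m / m_ref.
    """
    if m_ref == 0:
        raise ValueError("reference molality must be non-zero")
    return delta_gamma_value * np.asarray(molalities, dtype=float) / m_ref
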