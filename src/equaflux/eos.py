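"""Seawater thermodynamics helpers.

A compact, self-consistent equation of state for the upper tropical ocean:
potential density anomaly with a quadratic-in-temperature thermal expansion
and a constant haline contraction coefficient.  The expansion/contraction
coefficients returned by :func:`thermal_expansion` and
:func:`haline_contraction` are the exact analytic derivatives of
:func:`sigma0`, so buoyancy-frequency formulas written in terms of
(alpha, beta) agree with density-gradient formulations by construction.

Valid over roughly 0-32 degC and 30-40 g/kg, i.e. the upper 200 m of the
equatorial Atlantic; accuracy against full TEOS-10 is a few 1e-2 kg/m3,
ample for synthetic closed-loop work.
"""

from __future__ import annotations

import numpy as np

#: reference density (kg m-3)
RHO0 = 1025.0
#: gravitational acceleration (m s-2)
G = 9.81

# sigma0 reference point: sigma0(T_REF, S_REF) = SIGMA_REF
_T_REF = 10.0       # degC
_S_REF = 35.0       # g/kg
_SIGMA_REF = 26.95  # kg/m3

# thermal expansion alpha(T) = _A0 + _A1*(T - _T_REF), K-1
_A0 = 1.7e-4
_A1 = 8.5e-6
# haline contraction, kg/g
_BETA = 7.6e-4


def thermal_expansion(ct):
    """Thermal expansion coefficient alpha (K-1) at conservative temperature ct."""
    return _A0 + _A1 * (np.asarray(ct, float) - _T_REF)


def haline_contraction(ct=None):
    """Haline contraction coefficient beta (kg g-1); constant in this EOS."""
    if ct is None:
        return _BETA
    return np.full_like(np.asarray(ct, float), _BETA)


def sigma0(sa, ct):
    """Potential density anomaly sigma_Theta (kg m-3) referenced to the surface.

    Parameters
    ----------
    sa : array_like
        Absolute salinity, g/kg.
    ct : array_like
        Conservative temperature, degC.
    """
    sa = np.asarray(sa, float)
    ct = np.asarray(ct, float)
    dt = ct - _T_REF
    # integral of alpha(T) dT between T_REF and ct
    alpha_int = _A0 * dt + 0.5 * _A1 * dt**2
    return _SIGMA_REF + RHO0 * (_BETA * (sa - _S_REF) - alpha_int)


def rho(sa, ct):
    """In-situ density approximation (kg m-3), surface-referenced."""
    return 1000.0 + sigma0(sa, ct)


def kinematic_viscosity(ct=None):
    """Kinematic viscosity of seawater nu (m2 s-1).

    Exponential fit nu = 1.79e-6 * exp(-0.025 T), within a few percent of
    tabulated seawater values over 0-30 degC.  With ``ct=None`` a fixed
    default of 1.2e-6 m2/s is returned (temperature record unavailable).
    """
    if ct is None:
        return 1.2e-6
    return 1.79e-6 * np.exp(-0.025 * np.asarray(ct, float))


# hydrostatic dbar-per-metre at the reference density
_DBAR_PER_M = RHO0 * G / 1.0e4


def depth_to_pressure(z):
    """Hydrostatic depth (m, positive down) to pressure (dbar)."""
    return np.asarray(z, float) * _DBAR_PER_M


def pressure_to_depth(p):
    """Pressure (dbar) to depth (m, positive down)."""
    return np.asarray(p, float) / _DBAR_PER_M
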