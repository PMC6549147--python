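"""Seawater equation of state (EOS-80) utilities.

Potential density anomaly referenced to the surface (sigma-0) is the working
density variable of the whole pipeline: it defines the mixed layer depth, the
gridded density climatology and the alongstream density contrast.  The
routines here implement the UNESCO/EOS-80 formulation (international equation
of state of seawater, 1980, with the adiabatic lapse rate of Bryden 1973 as
standardised by Fofonoff & Millard 1983).  Inputs are practical salinity,
in-situ temperature in deg C (ITS-68 scale is assumed; the <0.01 K scale
difference is far below every tolerance used downstream) and pressure in dbar.

All functions are vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "density_at_surface",
    "adiabatic_lapse_rate",
    "potential_temperature",
    "sigma0",
    "potential_temperature_from_sigma0",
]


def density_at_surface(psal, temp):
    """Density of seawater at zero pressure, kg m^-3 (EOS-80 one-atmosphere term).

    Check value: density_at_surface(35, 5) = 1027.67547 kg m^-3.
    """
    S = np.asarray(psal, dtype=float)
    T = np.asarray(temp, dtype=float)
    # pure-water term (Bigg 1967, refitted)
    rho_w = (
        999.842594
        + T * (6.793952e-2
               + T * (-9.095290e-3
                      + T * (1.001685e-4
                             + T * (-1.120083e-6 + T * 6.536332e-9))))
    )
    A = (
        8.24493e-1
        + T * (-4.0899e-3 + T * (7.6438e-5 + T * (-8.2467e-7 + T * 5.3875e-9)))
    )
    B = -5.72466e-3 + T * (1.0227e-4 - T * 1.6546e-6)
    C = 4.8314e-4
    return rho_w + S * (A + B * np.sqrt(S) + C * S)


def adiabatic_lapse_rate(psal, temp, pres):
    """Adiabatic temperature gradient, deg C per dbar (Bryden 1973).

    Check value: adiabatic_lapse_rate(40, 40, 10000) = 3.255976e-4 deg C/dbar.
    """
    S = np.asarray(psal, dtype=float)
    T = np.asarray(temp, dtype=float)
    P = np.asarray(pres, dtype=float)
    ds = S - 35.0
    return (
        3.5803e-5 + T * (8.5258e-6 + T * (-6.836e-8 + T * 6.6228e-10))
        + ds * (1.8932e-6 - T * 4.2393e-8)
        + P * (1.8741e-8 + T * (-6.7795e-10 + T * (8.733e-12 - T * 5.4481e-14))
               + ds * (-1.1351e-10 + T * 2.7759e-12)
               + P * (-4.6206e-13 + T * (1.8676e-14 - T * 2.1687e-16)))
    )


def potential_temperature(psal, temp, pres, pres_ref=0.0):
    """Potential temperature, deg C, by 4th-order Runge-Kutta integration of
    the adiabatic lapse rate from ``pres`` to ``pres_ref`` (Fofonoff & Millard
    1983, UNESCO TR 44).

    Check value: potential_temperature(40, 40, 10000, 0) = 36.89073 deg C.
    """
    S = np.asarray(psal, dtype=float)
    T = np.asarray(temp, dtype=float)
    P = np.asarray(pres, dtype=float)
    dP = np.asarray(pres_ref, dtype=float) - P

    dT1 = dP * adiabatic_lapse_rate(S, T, P)
    th1 = T + 0.5 * dT1
    q1 = dT1

    dT2 = dP * adiabatic_lapse_rate(S, th1, P + 0.5 * dP)
    th2 = th1 + (1.0 - 1.0 / np.sqrt(2.0)) * (dT2 - q1)
    q2 = (2.0 - np.sqrt(2.0)) * dT2 + (-2.0 + 3.0 / np.sqrt(2.0)) * q1

    dT3 = dP * adiabatic_lapse_rate(S, th2, P + 0.5 * dP)
    th3 = th2 + (1.0 + 1.0 / np.sqrt(2.0)) * (dT3 - q2)
    q3 = (2.0 + np.sqrt(2.0)) * dT3 + (-2.0 - 3.0 / np.sqrt(2.0)) * q2

    dT4 = dP * adiabatic_lapse_rate(S, th3, P + dP)
    return th3 + (dT4 - 2.0 * q3) / 6.0


def sigma0(psal, temp, pres):
    """Potential density anomaly referenced to the surface, kg m^-3.

    sigma-0 = rho(S, theta(S, T, P -> 0), 0) - 1000.
    """
    theta = potential_temperature(psal, temp, pres, 0.0)
    return density_at_surface(psal, theta) - 1000.0


def potential_temperature_from_sigma0(sigma0_target, psal, tol=1e-10, max_iter=80):
    """Invert sigma-0 for potential temperature at fixed salinity.

    For practical salinity above ~24.7 surface density is strictly decreasing
    in temperature over the oceanographic range, so bisection on
    [-2.5, 40] deg C converges unconditionally.  Used by the synthetic-data
    generators to manufacture T/S profiles with a prescribed density structure.

    Raises ``ValueError`` if any target lies outside the attainable range.
    """
    tgt = np.asarray(sigma0_target, dtype=float)
    S = np.broadcast_to(np.asarray(psal, dtype=float), tgt.shape).copy()
    lo = np.full(tgt.shape, -2.5)
    hi = np.full(tgt.shape, 40.0)
    f_lo = density_at_surface(S, lo) - 1000.0 - tgt
    f_hi = density_at_surface(S, hi) - 1000.0 - tgt
    if np.any(f_lo < 0) or np.any(f_hi > 0):
        raise ValueError("sigma0 target outside attainable range for given salinity")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = density_at_surface(S, mid) - 1000.0 - tgt
        take_hi = f_mid > 0  # still denser than target -> warm up
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)
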