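"""Air-sea DMS exchange: Schmidt number, transfer velocities, flux.

Two k600(u10) parameterizations are provided:

* ``"yang"`` -- a polynomial reconstruction of gas transfer velocities
  derived from binned eddy-covariance DMS flux measurements (bubble-free
  interfacial transfer; converted from a Schmidt number of 660 to 600).
  DMS is highly soluble, so its transfer velocity grows much more slowly
  with wind than dual-tracer fits at high winds.
* ``"nightingale"`` -- the dual-tracer quadratic-plus-linear form,
  k600 = 0.222 u10^2 + 0.333 u10 (cm h-1), zero at zero wind.

The two agree closely below ~8 m s-1 and diverge above, the eddy-covariance
curve falling below the dual-tracer one.
"""

from __future__ import annotations

import warnings

import numpy as np

SCHMIDT_REF = 600.0

#: Sc_DMS(T) polynomial in T (deg C), ascending powers (Saltzman-type fit)
SALTZMAN_POLY = (2674.0, -147.12, 3.726, -0.038)
SCHMIDT_T_RANGE = (-2.0, 35.0)

#: k600(u10) cm h-1, ascending powers; fit to bubble-free binned DMS data
YANG_POLY = (0.0, 0.85, 0.075)
#: highest binned wind speed of the underlying data; clamp beyond it
YANG_U10_MAX = 15.0

#: k600 = NIGHTINGALE_COEFFS[0] * u10 + NIGHTINGALE_COEFFS[1] * u10^2 (cm h-1)
NIGHTINGALE_COEFFS = (0.333, 0.222)

METHODS = ("yang", "nightingale")


def schmidt_dms(T):
    """Schmidt number of DMS in seawater at temperature ``T`` (deg C).

    Positive and strictly decreasing over the fit range [-2, 35] deg C;
    temperatures outside that range are clamped with a warning.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = SCHMIDT_T_RANGE
    if np.any(T < lo) or np.any(T > hi):
        warnings.warn(
            f"temperature outside Schmidt-number fit range {SCHMIDT_T_RANGE}; clamping",
            stacklevel=2,
        )
        T = np.clip(T, lo, hi)
    a0, a1, a2, a3 = SALTZMAN_POLY
    sc = a0 + a1 * T + a2 * T * T + a3 * T ** 3
    return sc if sc.ndim else float(sc)


def k600(u10, method: str = "yang"):
    """Gas transfer velocity normalized to Sc = 600, in cm h-1."""
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    if method == "yang":
        u = np.minimum(u, YANG_U10_MAX)
        c0, c1, c2 = YANG_POLY
        k = c0 + c1 * u + c2 * u * u
    elif method == "nightingale":
        a, b = NIGHTINGALE_COEFFS
        k = a * u + b * u * u
    else:
        raise ValueError(f"unknown k600 method {method!r}; expected one of {METHODS}")
    return k if k.ndim else float(k)


def k_dms(u10, T, method: str = "yang", schmidt_exponent: float = -0.5):
    """DMS transfer velocity in m h-1: k600 * (Sc_DMS/600)**exponent."""
    k = np.asarray(k600(u10, method), dtype=float)
    sc = np.asarray(schmidt_dms(T), dtype=float)
    out = k * (sc / SCHMIDT_REF) ** schmidt_exponent / 100.0  # cm -> m
    return out if out.ndim else float(out)


def dms_flux(dms, u10, T, method: str = "yang", depth_m: float | None = None):
    """Air-sea DMS flux for seawater concentration ``dms`` (mmolS m-3).

    Atmospheric DMS is taken as zero.  Returns the areal flux in
    umolS m-2 h-1, or a ``(flux, volumetric_sink)`` pair when ``depth_m``
    is given (sink in mmolS m-3 h-1).
    """
    dms_arr = np.asarray(dms, dtype=float)
    if np.any(dms_arr < 0):
        raise ValueError("DMS concentration must be non-negative")
    k = np.asarray(k_dms(u10, T, method), dtype=float)
    flux_mmol = k * dms_arr  # mmolS m-2 h-1
    flux = flux_mmol * 1000.0  # umolS m-2 h-1
    flux = flux if flux.ndim else float(flux)
    if depth_m is None:
        return flux
    if depth_m <= 0:
        raise ValueError("depth must be positive")
    sink = flux_mmol / depth_m
    return flux, (sink if np.asarray(sink).ndim else float(sink))
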