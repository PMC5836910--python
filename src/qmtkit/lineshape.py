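"""Super-Lorentzian absorption lineshape of the macromolecular (bound) pool.

The bound pool in the two-pool MT model is saturated by off-resonance
irradiation at a rate ``RRFB = pi * omega1**2 * G(delta)``, where ``G`` is
the orientation-averaged (super-Lorentzian) absorption lineshape

    G(delta) = int_0^{pi/2} sin(phi) * sqrt(2/pi)
               * (t2b / |3 cos^2(phi) - 1|)
               * exp(-2 * (2 pi delta t2b / (3 cos^2(phi) - 1))**2) dphi

with ``delta`` the offset frequency in Hz and ``t2b`` the bound-pool T2 in
seconds.  The integrand has an integrable singularity at the magic angle
(3 cos^2(phi) = 1) and the integral diverges as ``delta -> 0``, so the
on-resonance flank is not physically meaningful within this model.

Two implementation choices matter:

* ``G`` obeys the exact scaling ``G(delta, t2b) = t2b * Ghat(delta * t2b)``,
  so a single one-dimensional profile ``Ghat`` is tabulated once by
  adaptive quadrature (with the magic-angle point declared to the
  integrator) and interpolated in log-log space.  The table is dense
  enough that interpolation error is far below the 1e-6 relative level
  probed by the tests.
* Below a configurable cutoff (default 1 kHz) ``G`` is evaluated by cubic
  extrapolation through anchor points at 1, 1.5, 2 and 3 kHz, a standard
  regularization of the super-Lorentzian for low-offset measurements.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import InterpolatedUnivariateSpline

__all__ = ["super_lorentzian_g", "saturation_rate_rrfb", "LOW_OFFSET_CUTOFF_HZ"]

_SQRT_2_PI = np.sqrt(2.0 / np.pi)
_MAGIC = 1.0 / np.sqrt(3.0)

#: offsets below this magnitude use the cubic anchor-point interpolation
LOW_OFFSET_CUTOFF_HZ = 1000.0
_ANCHORS_HZ = np.array([1000.0, 1500.0, 2000.0, 3000.0])


def _ghat_integrand(x: float, y: float) -> float:
    # x = cos(phi); y = delta * t2b (dimensionless); t2b scaled out
    u = 3.0 * x * x - 1.0
    arg = 2.0 * np.pi * y / u
    return _SQRT_2_PI / abs(u) * np.exp(-2.0 * arg * arg)


def ghat_quadrature(y: float) -> float:
    """Adaptive-quadrature evaluation of the unit-T2B lineshape Ghat(y)."""
    y = float(abs(y))
    if y == 0.0:
        raise ValueError("super-Lorentzian lineshape diverges at zero offset")
    val, _ = quad(_ghat_integrand, 0.0, 1.0, args=(y,), points=[_MAGIC],
                  limit=400, epsabs=0.0, epsrel=1e-12)
    return val


_GHAT_Y_LO, _GHAT_Y_HI = 2e-4, 6.0
_ghat_spline = None


def _get_spline() -> InterpolatedUnivariateSpline:
    global _ghat_spline
    if _ghat_spline is None:
        y = np.geomspace(_GHAT_Y_LO, _GHAT_Y_HI, 1400)
        g = np.array([ghat_quadrature(v) for v in y])
        _ghat_spline = InterpolatedUnivariateSpline(np.log(y), np.log(g), k=3, ext=2)
    return _ghat_spline


def _ghat(y: np.ndarray) -> np.ndarray:
    """Vectorized Ghat via the log-log table, quadrature outside its range."""
    y = np.abs(np.asarray(y, dtype=float))
    if np.any(y <= 0.0):
        raise ValueError("super-Lorentzian lineshape requires a nonzero offset")
    out = np.empty_like(y)
    inside = (y >= _GHAT_Y_LO) & (y <= _GHAT_Y_HI)
    if np.any(inside):
        out[inside] = np.exp(_get_spline()(np.log(y[inside])))
    if np.any(~inside):
        out[~inside] = [ghat_quadrature(v) for v in np.atleast_1d(y[~inside])]
    return out


def super_lorentzian_g(offset_hz, t2b, *, low_offset_cutoff_hz: float = LOW_OFFSET_CUTOFF_HZ):
    """Lineshape value G(offset, t2b) in seconds.

    Parameters
    ----------
    offset_hz : float or array
        Offset frequency of the irradiation (Hz).  G is even in the offset.
    t2b : float or array
        Bound-pool transverse relaxation time (s), strictly positive.
    low_offset_cutoff_hz : float
        Offsets with ``|offset| < cutoff`` are evaluated by a cubic fit
        through anchor points at 1, 1.5, 2 and 3 kHz (computed at the same
        ``t2b``), avoiding the on-resonance divergence.
    """
    offset = np.asarray(offset_hz, dtype=float)
    t2b_arr = np.asarray(t2b, dtype=float)
    if np.any(t2b_arr <= 0.0):
        raise ValueError("t2b must be strictly positive")
    offset, t2b_arr = np.broadcast_arrays(offset, t2b_arr)
    out = np.empty(offset.shape, dtype=float)
    absoff = np.abs(offset)
    low = absoff < low_offset_cutoff_hz
    high = ~low
    if np.any(high):
        out[high] = t2b_arr[high] * _ghat(absoff[high] * t2b_arr[high])
    if np.any(low):
        # cubic through the four anchors, evaluated per distinct t2b
        t2b_low = t2b_arr[low]
        off_low = absoff[low]
        vals = np.empty(off_low.shape)
        for tb in np.unique(t2b_low):
            sel = t2b_low == tb
            g_anchor = tb * _ghat(_ANCHORS_HZ * tb)
            coeff = np.polynomial.polynomial.polyfit(_ANCHORS_HZ, g_anchor, 3)
            vals[sel] = np.polynomial.polynomial.polyval(off_low[sel], coeff)
        out[low] = vals
    if out.ndim == 0:
        return float(out)
    return out


def saturation_rate_rrfb(omega1, offset_hz, t2b):
    """Bound-pool saturation rate RRFB = pi * omega1**2 * G (s^-1).

    ``omega1`` is the irradiation amplitude in rad/s; zero amplitude gives
    exactly zero saturation without evaluating the lineshape.
    """
    omega1 = np.asarray(omega1, dtype=float)
    if np.any(omega1 < 0.0):
        raise ValueError("omega1 must be non-negative")
    out = np.zeros(np.broadcast_shapes(omega1.shape, np.shape(offset_hz), np.shape(t2b)))
    nz = np.broadcast_to(omega1 != 0.0, out.shape)
    if np.any(nz):
        g = np.broadcast_to(super_lorentzian_g(offset_hz, t2b), out.shape)
        w = np.broadcast_to(omega1, out.shape)
        out[nz] = np.pi * w[nz] ** 2 * g[nz]
    if out.ndim == 0:
        return float(out)
    return out
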