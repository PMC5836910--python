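"""Independent high-accuracy integrator for the two-pool Bloch system.

Integrates dM/dt = L(t) M segment by segment with an adaptive explicit
Runge-Kutta method (DOP853, rtol 1e-10), entirely bypassing the package's
matrix-exponential propagation path.
"""

import numpy as np
from scipy.integrate import solve_ivp

from qmtkit.model import generator_matrix


def propagate_ode(waveform, tissue, offset_hz, m0):
    """Reference solution of the piecewise-constant two-pool Bloch equation."""
    m = np.asarray(m0, dtype=float)
    for omega1, duration in waveform.segments:
        L = generator_matrix(tissue, omega1, offset_hz)
        sol = solve_ivp(lambda t, y: L @ y, (0.0, duration), m,
                        method="DOP853", rtol=1e-10, atol=1e-13)
        if not sol.success:
            raise RuntimeError(f"ODE oracle failed: {sol.message}")
        m = sol.y[:, -1]
    return m
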