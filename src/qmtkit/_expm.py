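"""Batched matrix exponential for stacks of small dense matrices.

The propagation engine multiplies together thousands of ``exp(L * dt)``
factors for 5x5 generator matrices.  SciPy's ``expm`` handles stacked input
but pays per-matrix overhead; this module implements the classic
Pade(13) scaling-and-squaring evaluation with every step expressed as a
batched ``numpy`` operation, so the cost is dominated by vendor BLAS.
Accuracy is that of the standard algorithm (checked against
``scipy.linalg.expm`` in the test suite).
"""

from __future__ import annotations

import numpy as np

# Pade(13) numerator/denominator coefficients (Higham 2005).
_B13 = (
    64764752532480000.0,
    32382376266240000.0,
    7771770303897600.0,
    1187353796428800.0,
    129060195264000.0,
    10559470521600.0,
    670442572800.0,
    33522128640.0,
    1323241920.0,
    40840800.0,
    960960.0,
    16380.0,
    182.0,
    1.0,
)
_THETA13 = 4.25  # conservative scaling threshold for double precision


def expm_batch(a: np.ndarray) -> np.ndarray:
    """exp(a) for an array of shape (..., n, n).

    Each matrix is scaled by a power of two chosen from its own 1-norm,
    passed through the Pade(13) rational approximant, then squared back.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"expected (..., n, n) matrix stack, got shape {a.shape}")
    shape = a.shape
    a = np.ascontiguousarray(a).reshape(-1, shape[-2], shape[-1])
    norm = np.abs(a).sum(axis=-2).max(axis=-1)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("non-finite generator matrix passed to expm_batch")
    with np.errstate(divide="ignore"):
        s = np.ceil(np.log2(np.maximum(norm, 1e-300) / _THETA13))
    s = np.maximum(s, 0).astype(np.int64)
    a = a / (2.0 ** s)[..., None, None]

    b = _B13
    eye = np.eye(a.shape[-1])
    a2 = a @ a
    a4 = a2 @ a2
    a6 = a2 @ a4
    u = a @ (a6 @ (b[13] * a6 + b[11] * a4 + b[9] * a2)
             + b[7] * a6 + b[5] * a4 + b[3] * a2 + b[1] * eye)
    v = (a6 @ (b[12] * a6 + b[10] * a4 + b[8] * a2)
         + b[6] * a6 + b[4] * a4 + b[2] * a2 + b[0] * eye)
    r = np.linalg.solve(v - u, v + u)

    smax = int(s.max(initial=0))
    for k in range(smax):
        need = s > k
        if need.all():
            r = r @ r
        else:
            r[need] = r[need] @ r[need]
    return r.reshape(shape)


def matrix_power_batch(p: np.ndarray, n: int) -> np.ndarray:
    """p**n by binary exponentiation for a stack of shape (..., m, m)."""
    if n < 0:
        raise ValueError("negative matrix power not supported")
    out = np.broadcast_to(np.eye(p.shape[-1]), p.shape).copy()
    base = p.copy()
    while n:
        if n & 1:
            out = out @ base
        n >>= 1
        if n:
            base = base @ base
    return out
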