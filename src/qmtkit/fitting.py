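"""Voxel-wise estimation of (BPF, T2F, T2B, kFB) from normalized MT signals.

The fit works in normalized-ratio space: the data vector is the K
MT-weighted signals divided by the shuffled-average unsaturated reference,
and the model is the forward prediction of ``qmtkit.model``.  The observed
T1 enters as a constraint: at every iterate the free-pool R1 is re-derived
from (bpf, kfb, r1obs) with R1B held fixed, so only the four model
parameters are free.  Bounded trust-region least squares with a small
multi-start (central start plus seeded jitter) guards against the model's
known local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import Protocol, predict_signals_batch
from .params import R1B_DEFAULT, TissueParameters, derive_r1f

__all__ = ["FitOptions", "FitResult", "derive_r1f", "fit_qmt_voxel", "fit_qmt_maps",
           "PARAM_NAMES", "DEFAULT_LOWER", "DEFAULT_UPPER"]

PARAM_NAMES = ("bpf", "t2f", "t2b", "kfb")
DEFAULT_LOWER = np.array([0.005, 5e-3, 2e-6, 0.1])
DEFAULT_UPPER = np.array([0.5, 200e-3, 50e-6, 20.0])
_X_SCALE = np.array([0.1, 0.05, 1e-5, 2.0])
_R1F_FLOOR = 1e-4


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the voxel-wise qMT fit."""

    lower: np.ndarray = field(default_factory=lambda: DEFAULT_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: DEFAULT_UPPER.copy())
    n_starts: int = 5
    jitter: float = 0.5      # log-normal sigma of the multiplicative start jitter
    ftol: float = 1e-10
    xtol: float = 1e-8
    gtol: float = 1e-10
    r1b: float = R1B_DEFAULT
    seed: int | None = 0
    x0: np.ndarray | None = None   # overrides the central start when given


@dataclass(frozen=True)
class FitResult:
    tissue: TissueParameters | None   # None when every start failed
    residual_norm: float
    n_starts_used: int
    converged: bool
    bounds_hit: tuple

    @property
    def x(self) -> np.ndarray:
        """(bpf, t2f, t2b, kfb); NaN when the fit failed outright."""
        if self.tissue is None:
            return np.full(4, np.nan)
        return self.tissue.model_vector


def _r1f_from(bpf, kfb, r1obs, r1b):
    """Vectorized free-pool R1 from the observed longitudinal rate."""
    kbf = kfb * (1.0 - bpf) / bpf
    denom = r1b - r1obs + kbf
    r1f = r1obs - kfb * (r1b - r1obs) / denom
    return np.maximum(r1f, _R1F_FLOOR)


def _predict_x(x_stack: np.ndarray, protocol: Protocol, r1obs: float, r1b: float) -> np.ndarray:
    """Forward signals for a stack of (bpf, t2f, t2b, kfb) rows -> (M, K)."""
    x = np.atleast_2d(np.asarray(x_stack, dtype=float))
    bpf, t2f, t2b, kfb = x.T
    ts = {
        "bpf": bpf, "t2f": t2f, "t2b": t2b, "kfb": kfb,
        "r1f": _r1f_from(bpf, kfb, r1obs, r1b),
        "r1b": np.full(x.shape[0], r1b),
    }
    return predict_signals_batch(ts, protocol)


def _central_start(lower, upper) -> np.ndarray:
    return np.sqrt(lower * upper)


def fit_qmt_voxel(signals: np.ndarray, protocol: Protocol, t1obs: float,
                  options: FitOptions | None = None) -> FitResult:
    """Least-squares fit of one voxel's normalized signal vector.

    Parameters are bounded, the Jacobian is evaluated by batched central
    differences (one vectorized forward call per iteration), and the best
    of ``n_starts`` converged starts is returned.  If every start fails the
    result carries NaN parameters and ``converged=False``.
    """
    opts = options or FitOptions()
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (protocol.k,):
        raise ValueError(f"expected {protocol.k} normalized signals, got {signals.shape}")
    if protocol.k < 4:
        raise ValueError("need at least 4 measurements to fit 4 parameters")
    r1obs = 1.0 / t1obs
    lower, upper = np.asarray(opts.lower), np.asarray(opts.upper)

    def residual(x):
        return _predict_x(x, protocol, r1obs, opts.r1b)[0] - signals

    def jacobian(x):
        h = 1e-6 * np.abs(x) + 1e-12
        stack = np.repeat(x[None, :], 8, axis=0)
        for j in range(4):
            stack[2 * j, j] += h[j]
            stack[2 * j + 1, j] -= h[j]
        np.clip(stack, lower, upper, out=stack)
        preds = _predict_x(stack, protocol, r1obs, opts.r1b)
        cols = [(preds[2 * j] - preds[2 * j + 1]) / (stack[2 * j, j] - stack[2 * j + 1, j])
                for j in range(4)]
        return np.column_stack(cols)

    rng = np.random.default_rng(opts.seed)
    x_central = opts.x0 if opts.x0 is not None else _central_start(lower, upper)
    starts = [np.clip(np.asarray(x_central, dtype=float), lower, upper)]
    for _ in range(opts.n_starts - 1):
        jit = starts[0] * np.exp(opts.jitter * rng.standard_normal(4))
        starts.append(np.clip(jit, lower, upper))

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            res = least_squares(residual, x0, jac=jacobian, bounds=(lower, upper),
                                method="trf", x_scale=_X_SCALE,
                                ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return FitResult(tissue=None, residual_norm=float("nan"),
                         n_starts_used=n_used, converged=False,
                         bounds_hit=(False,) * 4)
    x = best.x
    tissue = TissueParameters(
        bpf=float(x[0]), t2f=float(x[1]), t2b=float(x[2]), kfb=float(x[3]),
        r1f=float(_r1f_from(x[0], x[3], r1obs, opts.r1b)), r1b=opts.r1b, t1obs=t1obs)
    atol = 1e-9 * _X_SCALE
    hit = tuple(bool(x[j] - lower[j] < atol[j] or upper[j] - x[j] < atol[j])
                for j in range(4))
    return FitResult(tissue=tissue, residual_norm=float(np.sqrt(2.0 * best.cost)),
                     n_starts_used=n_used, converged=bool(best.status > 0),
                     bounds_hit=hit)


def fit_qmt_maps(mt_volumes: np.ndarray, ref_volume: np.ndarray, t1_map: np.ndarray,
                 mask: np.ndarray, protocol: Protocol,
                 options: FitOptions | None = None, seed: int = 0) -> dict:
    """Voxel-independent qMT fitting over a masked volume.

    ``mt_volumes`` is (x, y, z, K), the reference and T1 maps are 3-D on
    the same grid.  Each voxel's multi-start jitter is seeded from
    ``(seed, flat voxel index)`` so results are deterministic and
    independent of mask traversal order.  Outside-mask voxels are NaN.
    """
    opts = options or FitOptions()
    mt = np.asarray(mt_volumes, dtype=float)
    names = {"ref_volume": np.asarray(ref_volume, dtype=float),
             "t1_map": np.asarray(t1_map, dtype=float),
             "mask": np.asarray(mask)}
    grid = mt.shape[:3]
    for name, vol in names.items():
        if vol.shape != grid:
            raise ValueError(f"{name} grid {vol.shape} does not match MT grid {grid}")
    if mt.shape[3] != protocol.k:
        raise ValueError(f"MT stack has {mt.shape[3]} volumes, protocol expects K={protocol.k}")
    maskb = names["mask"].astype(bool)
    if not maskb.any():
        raise ValueError("mask is empty")

    out = {name: np.full(grid, np.nan) for name in PARAM_NAMES}
    out["residual"] = np.full(grid, np.nan)
    out["converged"] = np.zeros(grid, dtype=bool)
    ref = names["ref_volume"]
    t1 = names["t1_map"]
    for idx in zip(*np.nonzero(maskb)):
        flat = int(np.ravel_multi_index(idx, grid))
        vox_opts = FitOptions(lower=opts.lower, upper=opts.upper,
                              n_starts=opts.n_starts, jitter=opts.jitter,
                              ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol,
                              r1b=opts.r1b,
                              seed=np.random.SeedSequence((seed, flat)).generate_state(1)[0],
                              x0=opts.x0)
        fit = fit_qmt_voxel(mt[idx] / ref[idx], protocol, float(t1[idx]), vox_opts)
        for j, name in enumerate(PARAM_NAMES):
            out[name][idx] = fit.x[j] if fit.converged else np.nan
        out["residual"][idx] = fit.residual_norm
        out["converged"][idx] = fit.converged
    return out
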