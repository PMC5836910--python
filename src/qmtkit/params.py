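"""Tissue parameter containers and reference parameter sets.

The two-pool MT model is parameterized by the bound pool fraction
BPF = M0B / (M0F + M0B), the free- and bound-pool transverse relaxation
times T2F (ms scale) and T2B (us scale), the forward exchange rate kFB
(s^-1, free -> bound), and the longitudinal rates R1F and R1B of the two
pools.  R1B is conventionally fixed (1 s^-1 here); R1F is not observable
directly and is derived from the measured mono-exponential T1obs through
the two-pool longitudinal eigenrate relation (see ``derive_r1f``).

All quantities are SI internally (seconds, Tesla, Hz, rad/s); conversion
to the customary ms / us reporting units is left to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TissueParameters",
    "derive_r1f",
    "tissue_from_t1obs",
    "default_tissue_set",
    "whole_cord_tissue",
    "R1B_DEFAULT",
]

#: conventional fixed bound-pool longitudinal rate (s^-1)
R1B_DEFAULT = 1.0


@dataclass(frozen=True)
class TissueParameters:
    """Model vector (bpf, t2f, t2b, kfb) plus relaxation context."""

    bpf: float        # bound pool fraction, dimensionless in (0, 1)
    t2f: float        # free-pool T2 (s)
    t2b: float        # bound-pool T2 (s)
    kfb: float        # forward exchange rate F -> B (s^-1)
    r1f: float        # free-pool longitudinal rate (s^-1)
    r1b: float = R1B_DEFAULT   # bound-pool longitudinal rate (s^-1)
    t1obs: float = float("nan")  # observed mono-exponential T1 (s), context only

    def __post_init__(self):
        if not 0.0 < self.bpf < 1.0:
            raise ValueError(f"bpf must lie strictly in (0, 1), got {self.bpf}")
        for name in ("t2f", "t2b", "r1f", "r1b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kfb < 0:
            raise ValueError("kfb must be non-negative")
        if self.t2b >= self.t2f:
            raise ValueError("t2b must be smaller than t2f (us vs ms scale)")

    @property
    def kbf(self) -> float:
        """Reverse exchange rate B -> F from detailed balance."""
        return self.kfb * (1.0 - self.bpf) / self.bpf

    @property
    def model_vector(self) -> np.ndarray:
        """(bpf, t2f, t2b, kfb) as an array, the fit/CRLB parameter order."""
        return np.array([self.bpf, self.t2f, self.t2b, self.kfb])

    def replace(self, **changes) -> "TissueParameters":
        return replace(self, **changes)


def derive_r1f(r1obs: float, bpf: float, kfb: float, r1b: float = R1B_DEFAULT) -> float:
    """Free-pool longitudinal rate consistent with an observed R1.

    Inverts the standard two-pool relation so that the slowest longitudinal
    eigenrate of the coupled relaxation-exchange system equals ``r1obs``:

        r1f = r1obs - kfb * (r1b - r1obs) / (r1b - r1obs + kfb * (1 - bpf) / bpf)

    Degenerate parameter combinations (vanishing denominator) raise.
    """
    if not 0.0 < bpf < 1.0:
        raise ValueError("bpf must lie strictly in (0, 1)")
    if kfb == 0.0:
        return float(r1obs)
    denom = r1b - r1obs + kfb * (1.0 - bpf) / bpf
    if abs(denom) < 1e-6:
        raise ValueError("degenerate tissue parameters: r1f relation denominator ~ 0")
    return float(r1obs - kfb * (r1b - r1obs) / denom)


def tissue_from_t1obs(bpf, t2f, t2b, kfb, t1obs, r1b: float = R1B_DEFAULT) -> TissueParameters:
    """Build a TissueParameters with r1f derived from the observed T1."""
    r1f = derive_r1f(1.0 / t1obs, bpf, kfb, r1b)
    return TissueParameters(bpf=bpf, t2f=t2f, t2b=t2b, kfb=kfb,
                            r1f=r1f, r1b=r1b, t1obs=t1obs)


# Healthy cervical-cord reference distributions used throughout the
# simulation studies: mean (SD) for BPF, T2F, T2B, kFB, T1obs.
_BASE_MEAN = dict(bpf=0.13, t2f=46.5e-3, t2b=11e-6, kfb=1.95, t1obs=1.1)
_BASE_SD = dict(bpf=0.02, t2f=5e-3, t2b=1e-6, kfb=0.2, t1obs=0.1)


def default_tissue_set(n_tissues: int = 6, r1b: float = R1B_DEFAULT) -> list:
    """Plausible tissue configurations for CRLB averaging.

    The set consists of the mean of the reference cord distributions, four
    variants perturbing one model parameter each by +1 SD, and one variant
    shifting every parameter by -1 SD.  Users optimizing for a different
    anatomy should supply their own list.
    """
    if n_tissues < 1:
        raise ValueError("need at least one tissue configuration")
    variants = [dict(_BASE_MEAN)]
    for key in ("bpf", "t2f", "t2b", "kfb"):
        v = dict(_BASE_MEAN)
        v[key] += _BASE_SD[key]
        variants.append(v)
    v = {k: _BASE_MEAN[k] - _BASE_SD[k] for k in _BASE_MEAN}
    variants.append(v)
    return [tissue_from_t1obs(r1b=r1b, **v) for v in variants[:n_tissues]]


def whole_cord_tissue() -> TissueParameters:
    """Whole-cord mean tissue (healthy adult cervical cord, 3T)."""
    return tissue_from_t1obs(bpf=0.11, t2f=46.5e-3, t2b=11.0e-6, kfb=1.95, t1obs=1.13)
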