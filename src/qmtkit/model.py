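"""Two-pool Bloch-McConnell forward model for MT-pulse-train preparation.

State vector and generator
--------------------------
Discarding the (microsecond-T2) transverse components of the bound pool,
the coupled two-pool Bloch equations are written homogeneously as
``dM/dt = L(t) M`` with

    M(t) = [1/2, MxA, MyA, MzA, MzB]^T

(the constant first element carries the equilibrium source terms; the
free-pool equilibrium magnetization is M0F = 1/2 so that the normalized
signal is exactly ``2 * MzA``).  The generator is

        [ 0        0        0        0        0          ]
        [ 0      -1/T2F   2 pi D     0        0          ]
    L = [ 0     -2 pi D  -1/T2F    w1(t)      0          ]
        [ R1F      0      -w1(t) -(R1F+kFB)  kBF         ]
        [ R1B*f    0        0       kFB    -(R1B+kBF+RRFB)]

with D the offset (Hz), w1(t) = 2 pi gamma_hz B1(t) the irradiation
amplitude (rad/s), kBF = kFB (1-BPF)/BPF, f = BPF/(1-BPF), and
RRFB = pi w1^2 G(D, T2B) the super-Lorentzian saturation rate of the
bound pool.

Propagation
-----------
The time-dependent w1(t) of a pulse train is replaced by a piecewise
constant approximation (default step eta = 100 us) and the state advanced
through matrix exponentials, ``M_out = prod_k exp(L_k d_k) M_in``, applied
in segment order.  Because every pulse in a train is identical, the
per-pulse propagator is computed once and the train assembled by a binary
matrix power; the cached and naive paths agree to machine precision.

A measurement of the shuffled multislice acquisition starts from thermal
equilibrium (full relaxation between shots), propagates the train plus a
post-train delay ``td``, and records ``2 * MzA``; the reported signal is
the average over the package's ``td`` values, emulating the slice-order
shuffling and signal averaging of the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._expm import expm_batch, matrix_power_batch
from .lineshape import super_lorentzian_g
from .params import TissueParameters
from .pulses import GAMMA_HZ, MTPulseSpec, TrainSpec, sample_envelope

__all__ = [
    "AcquisitionTiming",
    "SamplingPoint",
    "Protocol",
    "PiecewiseWaveform",
    "equilibrium_state",
    "generator_matrix",
    "discretize_waveform",
    "propagate",
    "predict_mt_signal",
    "predict_protocol",
    "predict_signals_batch",
]


# --------------------------------------------------------------------------
# sequence description types

@dataclass(frozen=True)
class AcquisitionTiming:
    """Timing of one slice package following the MT pulse train.

    ``td_list`` holds the delays (s) between the end of the train and each
    slice excitation within a package; ``fixed_block`` is the non-train
    portion of TR (readout, spoiling, dead time), so that
    TR = train duration + fixed_block.  ``eta`` is the waveform
    discretization step (s).
    """

    td_list: tuple = (18e-3, 112e-3, 206e-3, 300e-3)
    fixed_block: float = 6.302
    eta: float = 100e-6

    def __post_init__(self):
        td = np.asarray(self.td_list, dtype=float)
        if td.size == 0 or np.any(np.diff(td) <= 0):
            raise ValueError("td_list must be non-empty and strictly increasing")
        if np.any(td < 0):
            raise ValueError("delays must be non-negative")
        if self.eta <= 0:
            raise ValueError("eta must be strictly positive")
        object.__setattr__(self, "td_list", tuple(float(t) for t in td))

    @property
    def n_spp(self) -> int:
        """Slices per package (one delay per slice)."""
        return len(self.td_list)

    def tr(self, train: TrainSpec) -> float:
        """Repetition time for a given train (s)."""
        return train.duration + self.fixed_block


@dataclass(frozen=True)
class SamplingPoint:
    """One MT-weighted measurement: offset frequency and pulse amplitude."""

    offset: float   # Hz
    b1_peak: float  # T

    def __post_init__(self):
        if self.b1_peak < 0:
            raise ValueError("b1_peak must be non-negative")

    def flip_deg(self, duration: float, shape: str = "sinc_gaussian_no_lobes") -> float:
        from .pulses import effective_flip_angle
        return effective_flip_angle(
            MTPulseSpec(b1_peak=self.b1_peak, duration=duration, offset=self.offset, shape=shape))


@dataclass(frozen=True)
class Protocol:
    """K sampling points sharing one train template and package timing.

    The (implicit) unsaturated reference measurement is not counted in K;
    normalized signals are already ratios to that reference.
    """

    points: tuple
    train: TrainSpec
    timing: AcquisitionTiming
    snr_ref: float = 25.0
    name: str = ""

    def __post_init__(self):
        if len(self.points) < 1:
            raise ValueError("a protocol needs at least one sampling point")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def k(self) -> int:
        return len(self.points)

    def point_train(self, i: int) -> TrainSpec:
        """Train specification with point i's amplitude and offset filled in."""
        p = self.points[i]
        return self.train.with_pulse(b1_peak=p.b1_peak, offset=p.offset)

    def offsets(self) -> np.ndarray:
        return np.array([p.offset for p in self.points])

    def b1_peaks(self) -> np.ndarray:
        return np.array([p.b1_peak for p in self.points])


@dataclass(frozen=True)
class PiecewiseWaveform:
    """Ordered constant-amplitude segments (omega1 [rad/s], duration [s])."""

    segments: tuple

    def __post_init__(self):
        segs = tuple((float(w), float(d)) for w, d in self.segments)
        for w, d in segs:
            if d <= 0:
                raise ValueError("segment durations must be strictly positive")
            if w < 0:
                raise ValueError("segment amplitudes must be non-negative")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def amplitudes(self) -> np.ndarray:
        return np.array([w for w, _ in self.segments])

    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.segments])


# --------------------------------------------------------------------------
# generator matrix

def equilibrium_state(tissue: TissueParameters) -> np.ndarray:
    """Thermal equilibrium [1/2, 0, 0, 1/2, 1/2 * bpf/(1-bpf)]."""
    return np.array([0.5, 0.0, 0.0, 0.5, 0.5 * tissue.bpf / (1.0 - tissue.bpf)])


def _generator_stack(bpf, t2f, t2b, kfb, r1f, r1b, omega1, offset_hz, rrfb=None):
    """Generator matrices for broadcastable parameter arrays -> (..., 5, 5)."""
    bpf, t2f, t2b, kfb, r1f, r1b, omega1, offset = np.broadcast_arrays(
        *(np.asarray(a, dtype=float)
          for a in (bpf, t2f, t2b, kfb, r1f, r1b, omega1, offset_hz)))
    if rrfb is None:
        rrfb = np.zeros(bpf.shape)
        nz = omega1 != 0.0
        if np.any(nz):
            g = super_lorentzian_g(offset[nz], t2b[nz])
            rrfb[nz] = np.pi * omega1[nz] ** 2 * g
    two_pi_d = 2.0 * np.pi * offset
    kbf = kfb * (1.0 - bpf) / bpf
    L = np.zeros(bpf.shape + (5, 5))
    L[..., 1, 1] = -1.0 / t2f
    L[..., 1, 2] = two_pi_d
    L[..., 2, 1] = -two_pi_d
    L[..., 2, 2] = -1.0 / t2f
    L[..., 2, 3] = omega1
    L[..., 3, 0] = r1f
    L[..., 3, 2] = -omega1
    L[..., 3, 3] = -(r1f + kfb)
    L[..., 3, 4] = kbf
    L[..., 4, 0] = r1b * bpf / (1.0 - bpf)
    L[..., 4, 3] = kfb
    L[..., 4, 4] = -(r1b + kbf + rrfb)
    return L


def generator_matrix(tissue: TissueParameters, omega1: float, offset_hz: float) -> np.ndarray:
    """5x5 generator L for a single tissue at constant irradiation."""
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    return _generator_stack(tissue.bpf, tissue.t2f, tissue.t2b, tissue.kfb,
                            tissue.r1f, tissue.r1b, omega1, offset_hz)


# --------------------------------------------------------------------------
# waveform discretization and propagation

def _pulse_amplitudes(pulse: MTPulseSpec, eta: float) -> tuple:
    """(omega1 per segment, segment duration) midpoint-sampling the envelope."""
    if eta > pulse.duration:
        raise ValueError(
            f"discretization step eta={eta} exceeds pulse duration {pulse.duration}")
    n_seg = int(np.ceil(pulse.duration / eta))
    u = (np.arange(n_seg) + 0.5) / n_seg
    omega1 = 2.0 * np.pi * GAMMA_HZ * pulse.b1_peak * sample_envelope(pulse.shape, u)
    omega1 = np.abs(omega1)  # envelope tails may dip infinitesimally below zero
    return omega1, pulse.duration / n_seg


def discretize_waveform(train: TrainSpec, td: float, eta: float) -> PiecewiseWaveform:
    """Render a pulse train plus post-train delay as constant segments.

    Each pulse becomes ceil(tau/eta) equal-length segments sampling
    ``B1 * s(t)`` at segment midpoints; inter-pulse gaps and the trailing
    delay are single zero-amplitude segments.  Total duration equals
    N tau + (N-1) gap + td to machine precision.
    """
    if td < 0:
        raise ValueError("td must be non-negative")
    segs = []
    if train.n_pulses > 0:
        omega1, d = _pulse_amplitudes(train.pulse, eta)
        pulse_segs = [(w, d) for w in omega1]
        for i in range(train.n_pulses):
            if i > 0 and train.gap > 0:
                segs.append((0.0, train.gap))
            segs.extend(pulse_segs)
    if td > 0:
        segs.append((0.0, td))
    if not segs:
        raise ValueError("empty waveform: no pulses and zero post-train delay")
    return PiecewiseWaveform(tuple(segs))


def _segment_propagators(tissue: TissueParameters, offset_hz: float,
                         amplitudes: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """exp(L_k d_k) for each segment, deduplicating repeated (w1, d) pairs."""
    pairs = np.column_stack([amplitudes, durations])
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    L = _generator_stack(tissue.bpf, tissue.t2f, tissue.t2b, tissue.kfb,
                         tissue.r1f, tissue.r1b, uniq[:, 0], offset_hz)
    props = expm_batch(L * uniq[:, 1, None, None])
    return props[inverse]


def propagate(waveform: PiecewiseWaveform, tissue: TissueParameters,
              offset_hz: float, m0: np.ndarray) -> np.ndarray:
    """Apply the ordered product of segment exponentials to a state vector."""
    m0 = np.asarray(m0, dtype=float)
    if m0.shape != (5,):
        raise ValueError("state vector must have shape (5,)")
    props = _segment_propagators(tissue, offset_hz,
                                 waveform.amplitudes(), waveform.durations())
    m = m0
    for i, p in enumerate(props):
        m = p @ m
        if not np.all(np.isfinite(m)):
            raise FloatingPointError(f"non-finite state after segment {i}")
    return m


# --------------------------------------------------------------------------
# batched prediction engine

def _tissue_arrays(tissues) -> dict:
    """Stack a sequence of TissueParameters into per-field arrays."""
    return {name: np.array([getattr(t, name) for t in tissues])
            for name in ("bpf", "t2f", "t2b", "kfb", "r1f", "r1b")}


def _ordered_product(p: np.ndarray) -> np.ndarray:
    """prod over axis -3 in application order: P[..., S-1] @ ... @ P[..., 0]."""
    while p.shape[-3] > 1:
        if p.shape[-3] % 2:
            tail = p[..., -1:, :, :]
            p = np.concatenate([p[..., 1:-1:2, :, :] @ p[..., 0:-1:2, :, :], tail],
                               axis=-3)
        else:
            p = p[..., 1::2, :, :] @ p[..., 0::2, :, :]
    return p[..., 0, :, :]


_T_CHUNK = 256  # tissue-axis chunk bound on the (T, K, S, 5, 5) workspace


def predict_signals_batch(tissues, protocol: Protocol) -> np.ndarray:
    """Normalized MT-weighted signals for many tissues -> array (T, K).

    Vectorized over both tissue configurations and sampling points; this
    is the entry point used by the fitting, design and Monte Carlo layers.
    Large tissue batches are processed in chunks to bound memory.
    """
    ts = tissues if isinstance(tissues, dict) else _tissue_arrays(tissues)
    n_t = ts["bpf"].shape[0]
    if n_t <= _T_CHUNK:
        return _predict_block(ts, protocol)
    out = np.empty((n_t, protocol.k))
    for lo in range(0, n_t, _T_CHUNK):
        chunk = {k: v[lo:lo + _T_CHUNK] for k, v in ts.items()}
        out[lo:lo + _T_CHUNK] = _predict_block(chunk, protocol)
    return out


def _predict_block(ts: dict, protocol: Protocol) -> np.ndarray:
    train, timing = protocol.train, protocol.timing
    n_t = ts["bpf"].shape[0]
    b1s = protocol.b1_peaks()
    offs = protocol.offsets()
    out = np.ones((n_t, protocol.k))
    if train.n_pulses == 0:
        return out
    act = np.where(b1s > 0)[0]
    if act.size == 0:
        return out
    b1a, offa = b1s[act], offs[act]

    # omega1 per unit b1, sampled once; all points share it up to the b1 scale
    template = replace(train.pulse, b1_peak=1.0)
    env, d = _pulse_amplitudes(template, timing.eta)          # (S,), scalar
    uniq_env, inverse = np.unique(env, return_inverse=True)   # (U,), (S,)

    shp = (n_t, act.size, uniq_env.size)                       # (T, Ka, U)
    omega1 = b1a[None, :, None] * uniq_env[None, None, :]
    g = super_lorentzian_g(offa[None, :], ts["t2b"][:, None])  # (T, Ka)
    rrfb = np.pi * omega1 ** 2 * g[:, :, None]
    rrfb = np.broadcast_to(rrfb, shp).copy()
    fields = {k: ts[k][:, None, None] for k in ts}
    L = _generator_stack(fields["bpf"], fields["t2f"], fields["t2b"], fields["kfb"],
                         fields["r1f"], fields["r1b"], omega1,
                         offa[None, :, None], rrfb=rrfb)       # (T, Ka, U, 5, 5)
    seg_props = expm_batch(L * d)
    p_pulse = _ordered_product(seg_props[:, :, inverse])       # (T, Ka, 5, 5)

    fields0 = {k: ts[k][:, None] for k in ts}
    L0 = _generator_stack(fields0["bpf"], fields0["t2f"], fields0["t2b"],
                          fields0["kfb"], fields0["r1f"], fields0["r1b"],
                          0.0, offa[None, :])                  # (T, Ka, 5, 5)
    if train.n_pulses > 1:
        if train.gap > 0:
            cycle = expm_batch(L0 * train.gap) @ p_pulse
        else:
            cycle = p_pulse
        p_train = p_pulse @ matrix_power_batch(cycle, train.n_pulses - 1)
    else:
        p_train = p_pulse

    td = np.asarray(timing.td_list)
    p_td = expm_batch(L0[:, :, None] * td[None, None, :, None, None])

    m_eq = np.zeros((n_t, 5))
    m_eq[:, 0] = 0.5
    m_eq[:, 3] = 0.5
    m_eq[:, 4] = 0.5 * ts["bpf"] / (1.0 - ts["bpf"])
    m_train = np.einsum("tkij,tj->tki", p_train, m_eq)
    m_slices = np.einsum("tkdij,tkj->tkdi", p_td, m_train)
    out[:, act] = 2.0 * m_slices[..., 3].mean(axis=2)
    return out


def predict_mt_signal(tissue: TissueParameters, point: SamplingPoint,
                      train: TrainSpec, timing: AcquisitionTiming) -> float:
    """Normalized signal (2 * MzA averaged over the package delays).

    Equals 1 exactly with no saturation (zero amplitude or empty train).
    """
    protocol = Protocol(points=(point,), train=train, timing=timing)
    return float(predict_signals_batch([tissue], protocol)[0, 0])


def predict_protocol(tissue: TissueParameters, protocol: Protocol) -> np.ndarray:
    """K-vector of normalized signals for one tissue."""
    return predict_signals_batch([tissue], protocol)[0]
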