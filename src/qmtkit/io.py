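"""Protocol configuration (YAML) and NIfTI volume I/O.

Protocol schema
---------------
A protocol file is a YAML mapping with shared train/timing settings and a
per-point list::

    name: optimized
    shape: sinc_gaussian_no_lobes
    tau_ms: 15.0
    gap_ms: 15.0
    n_pulses: 25
    td_ms: [18.0, 112.0, 206.0, 300.0]
    fixed_block_ms: 6302.0
    eta_us: 100.0
    snr_ref: 25.0
    points:
      - {offset_hz: 1018.0, flip_deg: 378.0}
      - {offset_hz: 1000.0, b1_uT: 11.87}

Each point gives ``offset_hz`` plus either ``b1_uT`` or ``flip_deg`` (the
flip angle is converted through the registered pulse shape).  The two
protocols of the reference cervical-cord implementation ship as packaged
fixtures (``packaged_protocol("table_optimized" | "table_uniform")``).
"""

from __future__ import annotations

from importlib import resources
import nibabel as nib
import numpy as np
import yaml

from .model import AcquisitionTiming, Protocol, SamplingPoint
from .pulses import MTPulseSpec, TrainSpec, b1_peak_from_flip

__all__ = [
    "load_protocol", "save_protocol", "packaged_protocol", "protocol_to_dict",
    "load_volume", "load_mt_stack", "save_map",
]


def protocol_to_dict(protocol: Protocol) -> dict:
    train, timing = protocol.train, protocol.timing
    return {
        "name": protocol.name or "protocol",
        "shape": train.pulse.shape,
        "tau_ms": train.pulse.duration * 1e3,
        "gap_ms": train.gap * 1e3,
        "n_pulses": train.n_pulses,
        "td_ms": [td * 1e3 for td in timing.td_list],
        "fixed_block_ms": timing.fixed_block * 1e3,
        "eta_us": timing.eta * 1e6,
        "snr_ref": protocol.snr_ref,
        "points": [
            {"offset_hz": float(p.offset),
             "b1_uT": float(p.b1_peak * 1e6),
             "flip_deg": float(p.flip_deg(train.pulse.duration, train.pulse.shape))}
            for p in protocol.points
        ],
    }


def _protocol_from_dict(cfg: dict) -> Protocol:
    try:
        shape = cfg.get("shape", "sinc_gaussian_no_lobes")
        tau = float(cfg["tau_ms"]) * 1e-3
        train = TrainSpec(
            n_pulses=int(cfg["n_pulses"]),
            gap=float(cfg["gap_ms"]) * 1e-3,
            pulse=MTPulseSpec(b1_peak=0.0, duration=tau, offset=0.0, shape=shape),
        )
        timing = AcquisitionTiming(
            td_list=tuple(float(t) * 1e-3 for t in cfg["td_ms"]),
            fixed_block=float(cfg.get("fixed_block_ms", 6302.0)) * 1e-3,
            eta=float(cfg.get("eta_us", 100.0)) * 1e-6,
        )
        points = []
        for i, p in enumerate(cfg["points"]):
            offset = float(p["offset_hz"])
            if "b1_uT" in p:
                b1 = float(p["b1_uT"]) * 1e-6
            elif "flip_deg" in p:
                b1 = b1_peak_from_flip(float(p["flip_deg"]), tau, shape)
            else:
                raise KeyError(f"point {i}: needs b1_uT or flip_deg")
            points.append(SamplingPoint(offset=offset, b1_peak=b1))
    except KeyError as exc:
        raise ValueError(f"protocol config missing required field: {exc}") from exc
    return Protocol(points=tuple(points), train=train, timing=timing,
                    snr_ref=float(cfg.get("snr_ref", 25.0)),
                    name=str(cfg.get("name", "")))


def load_protocol(path) -> Protocol:
    """Read a protocol YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _protocol_from_dict(cfg)


def save_protocol(protocol: Protocol, path) -> None:
    """Write a protocol to YAML (amplitudes stored as both uT and degrees)."""
    with open(path, "w") as fh:
        yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False)


def packaged_protocol(name: str) -> Protocol:
    """Load one of the protocols shipped with the package."""
    ref = resources.files("qmtkit").joinpath("data", f"{name}.yaml")
    if not ref.is_file():
        have = sorted(p.stem for p in resources.files("qmtkit").joinpath("data").iterdir())
        raise ValueError(f"no packaged protocol {name!r}; available: {have}")
    return _protocol_from_dict(yaml.safe_load(ref.read_text()))


# --------------------------------------------------------------------------
# NIfTI I/O

def load_volume(path) -> nib.Nifti1Image:
    return nib.load(str(path))


def load_mt_stack(mt_path, ref_path, t1_path, mask_path, protocol: Protocol) -> dict:
    """Load and cross-validate the volumes of one fitting job.

    Checks 4-D measurement count against the protocol's K and grid/affine
    consistency across volumes; errors name the offending file.
    """
    imgs = {"mt": nib.load(str(mt_path)), "ref": nib.load(str(ref_path)),
            "t1": nib.load(str(t1_path)), "mask": nib.load(str(mask_path))}
    mt = imgs["mt"]
    if mt.ndim != 4:
        raise ValueError(f"{mt_path}: expected a 4-D MT stack, got {mt.ndim}-D")
    if mt.shape[3] != protocol.k:
        raise ValueError(
            f"{mt_path}: {mt.shape[3]} measurements but protocol has K={protocol.k}")
    grid = mt.shape[:3]
    for name, img in imgs.items():
        if img.shape[:3] != grid:
            raise ValueError(f"{name} volume grid {img.shape[:3]} != MT grid {grid}")
        if not np.allclose(img.affine, mt.affine, atol=1e-4):
            raise ValueError(f"{name} volume affine differs from the MT stack")
    return imgs


def save_map(data: np.ndarray, like: nib.Nifti1Image, path) -> None:
    """Write a parameter map with the geometry of an existing image."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             like.affine, like.header), str(path))
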