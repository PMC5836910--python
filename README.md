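# qmtkit

Quantitative magnetization transfer (qMT) modelling, fitting and
protocol design for MT-pulse-train-prepared multislice MRI — built for
small structures such as the cervical spinal cord, where scan-time
limits rule out steady-state MT preparation.

**Who it is for.** Researchers developing or simulating qMT acquisitions:
the package predicts the MT-weighted signal of a train-prepared,
slice-shuffled multislice sequence from first principles, estimates the
two-pool model parameters voxel-wise from image data, designs sampling
schemes by Cramér–Rao lower bound (CRLB) minimization, and quantifies
expected performance with seeded Monte Carlo studies on a digital
spinal-cord phantom.  No scanner data is required; everything can be
exercised end-to-end on synthetic data.

## The model in brief

Tissue is a two-pool system: free water protons (F) exchanging with
macromolecular-bound protons (B, T2 on the µs scale).  With the bound
pool's transverse terms eliminated, the state
`M = [½, MxA, MyA, MzA, MzB]ᵀ` evolves as `dM/dt = L(t) M`, where `L`
contains free-pool relaxation (R1F, T2F), off-resonance precession at
offset Δ, saturation ω₁(t) = 2πγB₁(t), exchange kFB and
kBF = kFB·(1−BPF)/BPF, and the bound-pool saturation rate
RRFB = π ω₁² G(Δ, T2B) with G the super-Lorentzian lineshape.  The free
parameters are the bound pool fraction **BPF**, the transverse
relaxation times **T2F** and **T2B**, and the exchange rate **kFB**;
R1F is constrained by a separate inversion-recovery T1 measurement.
Propagation through the discretized pulse train (η = 100 µs) uses the
matrix-exponential formalism; the normalized signal is 2·MzA averaged
over the package's post-train delays, emulating slice-order shuffling.

Sampling schemes are scored by the tissue-averaged weighted sum of
relative CRLBs, `V = Σᵢ wᵢ [F⁻¹]ᵢᵢ / pᵢ²` (w = [1,0,1,1] by default),
and the K (Δ, B₁) pairs are optimized with a seeded SOMA search under
peak-amplitude and SAR constraints.  See `docs/methods.md` for the full
account.

## Worked example

Predict the optimized 14-point protocol for healthy whole-cord tissue
(BPF 0.11, T2F 46.5 ms, T2B 11 µs, kFB 1.95 s⁻¹, T1obs 1.13 s), add
Rician noise at SNR 25, and fit the four parameters back:

```python
import numpy as np
from qmtkit import predict_protocol, whole_cord_tissue
from qmtkit.io import packaged_protocol
from qmtkit.fitting import fit_qmt_voxel, FitOptions
from qmtkit.studies import add_rician_noise

proto = packaged_protocol("table_optimized")
tissue = whole_cord_tissue()
sig = predict_protocol(tissue, proto)
print(np.round(sig, 4))

noisy = add_rician_noise(sig, 25.0, np.random.default_rng(42))
fit = fit_qmt_voxel(noisy, proto, t1obs=1.13, options=FitOptions(seed=0))
print(f"BPF={fit.x[0]:.3f}  T2F={fit.x[1]*1e3:.1f} ms  "
      f"T2B={fit.x[2]*1e6:.2f} us  kFB={fit.x[3]:.2f} /s")
```

prints

```
[0.7466 0.7437 0.7419 0.7579 0.7567 0.7549 0.7868 0.3824 0.5091 0.5148
 0.5109 0.5093 0.5123 0.7868]
BPF=0.119  T2F=45.0 ms  T2B=12.19 us  kFB=1.80 /s
```

The signal vector shows the protocol's structure: weak saturation at
low power / high offset (≈0.75–0.79) and strong saturation at the
high-power points near 1–3.5 kHz (≈0.38–0.51).  The noisy single-voxel
fit recovers the generating parameters to within the precision the CRLB
predicts at SNR 25 (theoretical CVs of roughly 14%, 9% and 15% for BPF,
T2B and kFB):

```python
from qmtkit.design import DesignConfig, crlb_report
rep = crlb_report(proto.points, proto.train, proto.timing, DesignConfig())
print(rep.cost, np.round(rep.cv_per_parameter, 3))
# 0.049  [0.138 0.486 0.092 0.146]
```

The same report for the conventional two-power-level ladder
(`packaged_protocol("table_uniform")`, N = 50) gives V = 0.182 — the
optimized scheme more than halves the weighted CRLB cost with half the
saturation train.

A command-line layer wraps the same functionality
(`qmtkit phantom | simulate | fit | optimize | sweep | mc | fieldsens |
interslice | report`); e.g.

```bash
qmtkit phantom --protocol prot.yaml --snr 50 --out phantom/
qmtkit fit --mt phantom/mt.nii --ref phantom/ref.nii --t1 phantom/truth_t1obs.nii \
           --mask phantom/mask.nii --protocol prot.yaml --out maps/
```

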