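# Methods

## The model

`qmtkit` implements a non-steady-state two-pool magnetization transfer
(MT) model for pulse-train-prepared multislice acquisitions.  Tissue is
described as a liquid (free, F) proton pool exchanging longitudinal
magnetization with a macromolecule-bound pool (B) whose transverse
relaxation is on the microsecond scale, so its transverse components are
dropped.  Writing the state homogeneously as
`M = [1/2, MxA, MyA, MzA, MzB]` (the constant first element carries the
relaxation source terms; M0F = 1/2 so the normalized signal is `2 MzA`),
the evolution under off-resonance irradiation of amplitude
`w1(t) = 2 pi gamma B1(t)` at offset `D` is `dM/dt = L(t) M` with

```
    [ 0        0        0         0          0              ]
    [ 0     -1/T2F    2 pi D      0          0              ]
L = [ 0    -2 pi D   -1/T2F     w1(t)        0              ]
    [ R1F      0      -w1(t)  -(R1F+kFB)    kBF             ]
    [ R1B f    0        0       kFB     -(R1B+kBF+RRFB)     ]
```

where `kBF = kFB (1-BPF)/BPF` (detailed balance), `f = BPF/(1-BPF)`, and
`RRFB = pi w1^2 G(D, T2B)` is the bound-pool saturation rate with `G`
the super-Lorentzian absorption lineshape.  The free model parameters
are `p = (BPF, T2F, T2B, kFB)`.  `R1B` is fixed at 1 s^-1 (it is
essentially unidentifiable and this is the conventional choice); `R1F`
is re-derived at every evaluation from the separately measured
mono-exponential `T1obs` by inverting the two-pool relation

```
R1F = R1obs - kFB (R1B - R1obs) / (R1B - R1obs + kBF)
```

so that the slowest longitudinal eigenrate of the exchange-relaxation
system equals `R1obs`.

### Lineshape

`G` is evaluated by adaptive quadrature of the standard fiber-angle
integral (with the magic-angle point declared to the integrator), using
the exact scaling `G(D, T2B) = T2B * Ghat(D * T2B)`: a single
1400-point log-log table of `Ghat` is built once and interpolated with a
cubic spline; interpolation error is below 1e-8 relative, verified
against brute-force quadrature.  The integral diverges on resonance, so
for |D| < 1 kHz `G` is evaluated by a cubic polynomial through anchor
values at 1, 1.5, 2 and 3 kHz (computed at the actual T2B) — needed for
the conventional protocol's 400 and 768 Hz points.  Both the cutoff and
the anchors are configurable.

### Pulse model and calibration

The MT pulse envelope `sinc_gaussian_no_lobes` is the main lobe of a
sinc apodized by a Gaussian (sigma = 0.45 tau/2).  Vendor envelopes of
this family differ in details; the only firm constraint is the flip-angle
calibration that a 12 uT, 15 ms pulse produces an effective flip angle
of 1480 deg.  The envelope is therefore rescaled once so its
shape factor `integral(s)/tau` is exactly `1480 / (360 gamma * 12uT * 15ms)
= 0.5364`; the factor is exposed programmatically and written into
protocol files so it can be audited.  `gamma = 42.577478518 MHz/T`.

### Propagation

`w1(t)` is replaced by a piecewise-constant approximation with step
`eta` (default 100 us; each pulse becomes `ceil(tau/eta)` equal segments
sampled at midpoints, gaps and post-train delays single zero segments)
and the state advanced by matrix exponentials.  Refining `eta` from
100 us to 10 us changes predicted signals by < 0.2%.

Because all pulses in a train are identical, the per-pulse propagator is
computed once and the train is assembled as
`P_pulse (P_gap P_pulse)^(N-1)` by binary matrix power; this caching
path agrees with naive segment-by-segment propagation to ~1e-14 and with
an adaptive ODE integration of the same piecewise system to better than
1e-4 relative.  Matrix exponentials are evaluated by a batched
Pade(13) scaling-and-squaring routine so that whole protocols, tissue
batches and finite-difference stencils are processed in single
vectorized calls.

A measurement starts from thermal equilibrium (TR >> T1, full relaxation
between shots), propagates the train plus a post-train delay `td`, and
records `2 MzA`.  Slice-order shuffling with signal averaging is
emulated by averaging over the package's `td` values
(18/112/206/300 ms by default).  Free-pool transverse components evolve
continuously through inter-pulse gaps (no artificial spoiling).

### Timing conventions

Train duration is counted as `N tau + (N-1) gap`, and `td` from the end
of the last pulse.  TR = train duration + `fixed_block`, with
`fixed_block` chosen to reproduce the reference sequence TRs (7037 ms at
N = 25, 7786 ms at N = 50, tau = gap = 15 ms); whether the sequence's
delays are counted from end-of-train or start-of-readout cannot be
disambiguated from the printed TR arithmetic, and the residual ambiguity
is a 1 ms difference in `fixed_block` with no effect on predictions.

## T1obs mapping

The inversion-recovery series (default eight TIs, 100 + k*350 ms) is
fitted voxel-wise with the rectified three-parameter magnitude model
`|m0 (1 - 2 e exp(-TI/T1))|` extended by a free Rician noise-floor term
(`sqrt(model^2 + floor^2)`): near the signal null the measured magnitude
is noise-dominated and the plain rectified fit biases T1 downward by
~2% at SNR 25, which the floor term reduces to ~0.5%.  Multi-start over
the null-point location removes the rectified model's sign ambiguity.
A polarity-restored variant is available behind a flag.

## Voxel-wise qMT fitting

Fitting works in normalized-ratio space (MT-weighted / shuffled-average
reference, assumed exactly normalized; the interslice study below
justifies this).  Bounded trust-region least squares over
`(BPF, T2F, T2B, kFB)` with bounds BPF [0.005, 0.5], T2F [5, 200] ms,
T2B [2, 50] us, kFB [0.1, 20] s^-1, tolerances ftol 1e-10 / xtol 1e-8 /
gtol 1e-10, characteristic-scale scaling, and a batched central-difference
Jacobian
(one vectorized forward call per iteration).  Map fitting uses five
starts (the geometric bound center plus seeded log-normal jitter),
seeded per voxel from (seed, flat index) so results are independent of
traversal order.  Simulation studies instead start from the mean of
their generating tissue set (single start): the realization truths are
small perturbations around it, so a literature-mean start is both
realistic and keeps paired protocol comparisons strictly paired.

## Protocol design

For Gaussian noise of sigma = 1/SNR on the normalized signal the Fisher
matrix is `F = SNR^2 J^T J`, with J the K x 4 signal Jacobian computed
by central differences (relative step 1e-3 with per-parameter floors).
The design cost is the weighted sum of relative CRLBs,
`V = sum_i w_i [F^-1]_ii / p_i^2`, arithmetically averaged over a set of
six plausible tissue configurations and with default weights (1, 0, 1, 1)
(T2F excluded: it is the least constrained parameter and its inclusion
promotes local minima).  The tissue set is the mean of the reference
cord distributions (BPF 0.13, T2F 46.5 ms, T2B 11 us, kFB 1.95 s^-1,
T1obs 1.1 s) plus four single-parameter +1 SD variants and one all-
parameter -1 SD variant (SDs 0.02, 5 ms, 1 us, 0.2 s^-1, 0.1 s);
user-overridable.

The 2K (offset, B1) variables are searched with the all-to-one
self-organizing migrating algorithm (SOMA) — default population 20,
migrations 40, PathLength 3.0, Step 0.11, PRT 0.1, fully seeded —
followed by an optional bounded Powell polish of the best point.
Offsets are searched in log10-space within [1, 100] kHz.  Constraints
are enforced by box reduction rather than penalties: the per-point B1
upper bound is the tighter of the 13 uT hardware cap and the amplitude
at which the normalized SAR surrogate reaches the cap, so every emitted
point is feasible by construction.  One individual of the initial
population is seeded with a conventional two-power-level log-spaced
ladder, which the search can only improve upon.

### SAR surrogate

Scanner SAR models are proprietary; the package uses
`u = N B1^2 integral(s^2) / TR`, normalized so that u = 1 for the
highest-power admissible configuration (12 uT peak, N = 25,
tau = gap = 15 ms, TR = 7037 ms).  This surrogate is self-consistent
with the reference protocols: the 1100 deg, N = 50 level evaluates to
u = 0.999, i.e. the same cap.  The published "80% / 30% of maximum SAR"
flip-angle pair (601/1100 deg) is not exactly reproducible under any
simple B1^2 duty-cycle surrogate, so the conventional protocol ships
with those flip angles as a fixture rather than re-deriving them.

### Heuristic timing search

The remaining sequence parameters (N, tau, gap) are chosen by sweeping
one parameter at a time and re-running the (offset, B1) optimization at
each grid value with identical seed and budget, making the V profile a
paired comparison.  Desk-scale sweeps use a reduced SOMA budget
(population 8, migrations 6, step 0.6 up to path length 1.8, PRT 0.3,
Powell polish capped at 80 evaluations) and a search-time discretization
of 250 us (V differs from the 100 us value by < 0.1%; final reports are
evaluated at the native step).  At this budget the search is roughly
3x shallower than the default, but the paired design preserves the
ranking of grid values, which is all the sweep consumes.

## Simulation studies

Monte Carlo recovery: per realization one of the six base tissues is
drawn and perturbed with SDs (0.02, 0.01 ms, 1 us, 0.4 s^-1) for
(BPF, T2F, T2B, kFB) — the T2F perturbation of 0.01 ms is used as
specified even though it is tiny relative to ~46 ms — signals are
simulated for every protocol, Rician noise `sqrt((s+n1)^2+n2^2)` with
sigma = 1/SNR is added using noise deviates shared across protocols,
and all four parameters are fitted with the generating T1obs.
Percentage errors are reported against the realization-specific truth;
fit failures are excluded and counted.  Default n = 200 per condition
(1000 reproduces the full-scale study).  B0/B1 sensitivity studies
generate signals with shifted offsets or scaled amplitudes and fit with
nominal values.

Interslice saturation: within a package of 4 slices (acquired 18 ms
after the train, then every 91 ms), each slice's spin-echo pair acts as
off-resonance irradiation on the others.  The published sequence does
not document the readout pulses, so the study makes explicit,
configurable assumptions: 90/180 deg Hann-apodized sinc pulses of 3 ms,
time-bandwidth 3 (bandwidth 1 kHz), refocusing 14 ms after excitation
(TE 28 ms), package slices 3 slice-widths apart so the nearest off-slice
offset is 3 kHz.  The study computes the raw saturation of the
shuffled-average reference image and the residual error of the core
model (which ignores these events) after normalization by that equally
affected reference; under the default assumptions the reference
saturation stays below 8% and the post-normalization residual below
0.8%, which is what justifies fitting in normalized-ratio space without
modelling the readout.

Reproducibility of repeated measurements is summarized by
`I = 1 - (max - min)/(2 mean)` per voxel and protocol distributions are
compared with the two-sample Kolmogorov-Smirnov test.

## The digital phantom

The phantom mimics the target acquisition geometry (64 x 52 voxels at
0.75 x 0.75 mm^2, 12 x 5 mm slices) with a circular cord of radius 4 mm
carrying the whole-cord reference parameters (BPF 0.11, T2F 46.5 ms,
T2B 11.0 us, kFB 1.95 s^-1, T1obs 1.13 s) and an optional grey-matter
butterfly (off by default; cord GM/WM BPF contrast is small).  Voxel
signals come from the package's own forward models plus seeded Rician
noise.  What the phantom does *not* emulate: partial-volume edges,
physiological noise and motion, B0/B1 inhomogeneity, EPI distortion and
slice-profile effects.  Passing phantom recovery therefore validates
the numerical pipeline (model, normalization, fitting), not robustness
to those real-data effects.

## Numerical choices and limitations

* Batched Pade(13) matrix exponentials with per-matrix scaling; agreement
  with `scipy.linalg.expm` at the 1e-13 level is enforced by tests.
* Degenerate inputs: BPF at {0, 1}, non-positive relaxation times, empty
  masks, mismatched grids and unresolvable discretization steps raise
  descriptive errors; singular Fisher matrices are penalized (1e12), not
  raised, inside design searches.
* Monte Carlo studies at n = 200 resolve IQR differences of the size
  seen between the two reference protocols, but not few-percent effects;
  the full-scale n = 1000 setting is one config field away.
* The heuristic timing search optimizes one parameter at a time; a joint
  search over (N, tau, gap, offsets, B1) is out of scope, as is any
  vendor-exact SAR model, image reconstruction, or motion/registration
  processing.
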