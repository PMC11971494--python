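# Methods

## Model

Probe phase is separable in space and time: `phi = P k`, with `P` the
probing matrix of real solid harmonics evaluated at the probe positions and
`k` the per-basis coefficient time-courses. The package uses unnormalized
tesseral regular solid harmonics

    S_l^m(r) = r^l P_l^|m|(cos θ) · {cos |m|φ (m ≥ 0), sin |m|φ (m < 0)},

without the Condon–Shortley phase, ordered by ascending degree `l` and
ascending `m` within each degree, evaluated with a stable Hobson-type
recursion directly in Cartesian coordinates. The first four functions are
`1, y, z, x`; the degree-2 row is `6xy, 3yz, (2z²−x²−y²)/2, 3xz, 3(x²−y²)`.
No normalization variant is claimed to match any vendor convention: because
the same basis is used for simulation, calibration, compression and
fitting, per-column scale factors cancel, and the package exposes
`HarmonicIndexing.index_map` so callers can relabel. Positions are in
meters, so row `i` of `k` carries rad/m^{l_i}.

## Fitting

`fit_k` solves the (optionally per-probe-weighted) least-squares problem
with `numpy.linalg.lstsq`; with weights it equals the normal-equations
solution `(PᵀW²P)⁻¹PᵀW²phi`, which the tests verify independently. The fit
refuses underdetermined systems and declares ill-posedness above a
condition number of 1e10 measured on the *column-equilibrated* design
matrix — solid-harmonic columns span many decades purely from their m^l
units, which is not a genuine deficiency; the error message names the
`(l, m)` pairs most aligned with the near-null space. Probe weighting
defaults to identity: the distal-probe weighting used on real systems is
system-specific, so the interface accepts a diagonal without prescribing
one. Weights apply to fitting only, not to the calibration SVD.

The concomitant-field refit uses the lowest-order symmetric-gradient
Maxwell term

    B_c = (Gx²z² + Gy²z² + Gz²(x²+y²)/4 − GxGz·xz − GyGz·yz) / (2 B0),

with the gradient waveform recovered from the time-derivative of the
fitted first-order k rows, its accrued phase `γ∫B_c dt` (reset at each
volume boundary) subtracted from `phi`, and the fit repeated — 2 iterations
by default with an early exit when max|Δk|/max|k| < 1e-6. The same routine
computes the concomitant phase in the simulator, so the correction loop is
testable end to end; the formula is the canonical symmetric-coil
expression and `γ` is configurable.

## Compression

`build_compression` takes the SVD of `Γ_high k_calib_high` (degrees ≥ 2,
`Γ_ii = gamma_base^{l_i}`, base 0.1 by default — equal weighting over a
1-dm radius). Multiple calibration scans are concatenated along time before
the SVD with no per-scan renormalization. Determinism: each retained
singular vector is flipped so its largest-magnitude entry is positive. `L`
may be an integer or a relative singular-value threshold; requests beyond
the numerical rank are clamped with a warning, as are calibrations shorter
than `Nb − 4` samples (rank-limited model). The compressed fit requires
`Np ≥ L + 4` and reports the maximum admissible `L` otherwise.

## Synthetic data

The generator emulates the measurement setting, not any particular scanner:

* **Waveforms.** PGSE (trapezoid pair scaled numerically to a requested
  b-value; defaults δ = 12 ms, Δ = 20 ms, b = 1000 s/mm²), OGSE (two
  raised-cosine-ramped oscillating lobes, default 40 Hz), slew-limited
  Archimedean spiral readout, EPI trapezoid train with blips, and linear
  chirp, all validated against 80 mT/m and 400 T/m/s limits at a 20 µs
  raster.
* **Eddy currents.** Each mode maps one gradient axis to one basis function
  through an LTI single-exponential response driven by the slew,
  `dB ∝ −dg/dt ⊛ e^{−t/τ}`. The k response is computed as the *exact*
  convolution integral for piecewise-constant gradients (kernel
  `τ(1−e^{−t/τ})` applied to per-sample gradient increments), so the step
  response matches the closed form to machine precision and no raster-rate
  discretization error enters. The sign convention is that the induced
  field opposes the gradient change.
* **Default scene.** Six modes on degrees 2–5 with τ = 0.1, 1, 5, 20, 50
  and 100 ms; amplitudes are first equalized in RMS probe-phase
  contribution, then globally scaled so degree-2+ phase is 8 % of the
  degree-0/1 phase over the 16-probe shell — the regime of probe mounts
  well outside the specified imaging volume. Phase noise is iid Gaussian,
  0.05 rad SD, seeded explicitly everywhere.
* **Probe layout.** A deterministic 16-probe shell (golden-angle azimuths,
  radii cycling 11.9–14.9 cm, mean 13.5 cm) replicated over three
  equiangular z-rotations and three one-sided 5-cm z-shifts (a head-coil
  mount slides out of the bore), filtered to ≤ 16 cm Euclidean and ≤ 14 cm
  per-axis distance — 144 candidates, 101 retained.
* **Directions.** Diffusion directions by electrostatic-repulsion descent
  on the 1/distance energy with antipodal symmetry, 1000-iteration cap;
  probe subsets by greedy farthest-point seeding plus exchange passes on
  the same criterion.

What the simulation does **not** contain: gradient-coil field
nonlinearity, probe T2* decay and resonance drift, mechanical vibration,
physiological field fluctuations, synchronization delay, and any spatial
eddy structure beyond degree 5. Passing tests therefore demonstrate the
algebra and the relative orderings (compressed vs conventional fits,
trade-off shapes, calibration transfer), not absolute error levels on any
real scanner.

## Evaluation

The RMSE metric weights row `i` by `0.1^{l_i}` (starting at degree 0),
averages squared differences over time within each volume, sums over the
first nine basis functions (degrees 0–2 — the rows whose errors drive
image artifacts), takes the square root, and then reports mean and SD
across volumes. Sweeps rebuild the truncated model per `L` (the SVD is
computed once and truncated, which is equivalent) and report medians across
seeds in the multi-seed studies for robustness to outliers.

## Study sizes and numerical choices

The packaged studies use 7 calibration volumes (1 b=0 + 6 directions) and
4 test volumes of ~2000–5000 samples each at a 20 µs raster, 25 seeds for
the headline and calibration-transfer studies and 50 for the trade-off
sweeps in the test suite; these sizes give stable medians while keeping a
full run to a few minutes. Identity tolerances follow matrix algebra at
double precision: 1e-10 for `CᵀC = I` and projector idempotence, 1e-8 for
least-squares equivalences that pass through `lstsq`. The harmonicity check
uses a 5-point central Laplacian stencil (exact for quintic polynomials),
since a 3-point stencil has genuine h² truncation error for degree ≥ 4.

## Known limitations

* One known structural gap: with iid phase noise the degree-0..2 RMSE of
  the compressed 16-probe fit sits at ~2× the 100-probe 5th-order fit —
  Fisher information scales with probe count, so a 16-probe fit cannot
  reach the 100-probe noise floor; its value is that it reaches the right
  order of magnitude at all, where the conventional 3rd-order fit is off
  by four orders.
* The eddy model is one basis function per mode; real spatial modes mix
  several harmonics. This changes nothing algebraically (the SVD learns
  mixed modes identically) but keeps ground truth interpretable.
* The automatic `L` selection minimizes RMSE against a supplied ground
  truth; on a real system ground truth requires a multi-position scan, and
  `L` would be chosen from the singular spectrum by inspection.
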