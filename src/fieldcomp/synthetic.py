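"""Synthetic gradient waveforms, eddy-current field dynamics, and probe data.

No public field-camera datasets exist, so validation runs on simulation.  The
generator emulates the measurement setting end to end:

* gradient waveforms for the sequence classes of interest (spiral readouts,
  EPI trains, PGSE/OGSE diffusion encodes, chirped calibration pulses) under
  head-gradient hardware limits (80 mT/m, 400 T/m/s by default);
* gradient-induced eddy currents as per-(basis function, gradient axis)
  linear time-invariant single-exponential responses driven by the slew rate,
  which is the standard model and produces the few dominant spatial modes
  that make high-order dynamics compressible;
* a multi-position calibration probe array (16-probe shell replicated over
  3 z-shifts × 3 rotations, then distance-filtered to ~100 positions) and the
  single-position 16-probe monitoring array;
* noisy probe phase via the forward model plus iid Gaussian phase noise.

All stochastic entry points take an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .harmonics import HarmonicIndexing, ProbeArray, evaluate_basis
from .fitting import GAMMA_PROTON, KCoefficients, PhaseData, concomitant_phase

__all__ = [
    "GradientWaveform",
    "EddyMode",
    "EddyGradientScene",
    "ProbeLayoutSpec",
    "InfeasibleWaveformError",
    "make_waveform",
    "simulate_k_true",
    "build_probe_array",
    "generate_monitoring_data",
    "uniform_directions",
    "repulsion_energy",
    "select_probe_subset",
]

#: Default hardware limits (head gradient): max amplitude T/m, max slew T/m/s.
DEFAULT_GMAX = 80e-3
DEFAULT_SMAX = 400.0
#: Default gradient raster time, s.
DEFAULT_DT = 2e-5


class InfeasibleWaveformError(ValueError):
    """Requested waveform violates the gradient hardware limits."""


@dataclass(frozen=True)
class GradientWaveform:
    """Three-axis gradient waveform at a fixed raster time.

    ``g`` is (3, Nt) in T/m; ``dt`` in seconds.
    """

    g: np.ndarray
    dt: float
    kind: str = "composite"
    gmax: float = DEFAULT_GMAX
    smax: float = DEFAULT_SMAX

    def __post_init__(self):
        g = np.atleast_2d(np.asarray(self.g, dtype=float))
        if g.shape[0] != 3:
            raise ValueError(f"g must be (3, Nt), got {g.shape}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "g", g)
        amp = np.max(np.abs(g))
        if amp > self.gmax * (1 + 1e-9):
            raise InfeasibleWaveformError(
                f"|g| = {amp * 1e3:.2f} mT/m exceeds limit {self.gmax * 1e3:.1f} mT/m")
        slew = np.max(np.abs(np.diff(g, axis=1))) / self.dt if g.shape[1] > 1 else 0.0
        if slew > self.smax * (1 + 1e-9):
            raise InfeasibleWaveformError(
                f"slew {slew:.1f} T/m/s exceeds limit {self.smax:.1f} T/m/s")

    @property
    def n_samples(self) -> int:
        return self.g.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def concat(self, other: "GradientWaveform") -> "GradientWaveform":
        if abs(other.dt - self.dt) > 1e-15:
            raise ValueError("raster times differ")
        return GradientWaveform(np.concatenate([self.g, other.g], axis=1),
                                self.dt, kind="composite",
                                gmax=max(self.gmax, other.gmax),
                                smax=max(self.smax, other.smax))


@dataclass(frozen=True)
class EddyMode:
    """One LTI eddy-current mode: gradient axis ``source_axis`` (0/1/2)
    drives basis function ``basis_index`` with amplitude ``amplitude`` and
    time constant ``tau`` (s).  The induced field opposes the gradient
    change: dB ∝ −dg/dt ⊛ exp(−t/τ)."""

    basis_index: int
    source_axis: int
    amplitude: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.basis_index < 0:
            raise ValueError("basis_index must be >= 0")
        if self.source_axis not in (0, 1, 2):
            raise ValueError("source_axis must be 0, 1 or 2")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class EddyGradientScene:
    """Ground-truth definition for one simulated acquisition."""

    waveform: GradientWaveform
    modes: tuple = ()
    gamma: float = GAMMA_PROTON
    noise_sd: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "modes", tuple(self.modes))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_waveform(self, waveform: GradientWaveform) -> "EddyGradientScene":
        return replace(self, waveform=waveform)


# ---------------------------------------------------------------------------
# Waveform generators
# ---------------------------------------------------------------------------

def _trapezoid(amplitude: float, flat_time: float, dt: float, smax: float) -> np.ndarray:
    """Symmetric trapezoid lobe sampled at dt (1-D array)."""
    ramp = abs(amplitude) / (0.95 * smax)
    n_ramp = max(1, int(np.ceil(ramp / dt)))
    n_flat = max(0, int(round(flat_time / dt)))
    up = np.linspace(0.0, amplitude, n_ramp + 1)[1:]
    return np.concatenate([up, np.full(n_flat, amplitude), up[::-1][1:], [0.0]])


def _pgse_pair(amplitude: float, delta: float, Delta: float, dt: float,
               smax: float) -> np.ndarray:
    """PGSE diffusion pair: two matched trapezoids, lobe onsets Δ apart.

    Both lobes have the same polarity; the refocusing pulse between them
    (not simulated) flips the effective sign of the second, so the pair is
    balanced in its diffusion action.  The *effective* waveform used for
    b-value bookkeeping negates the second lobe.
    """
    lobe = _trapezoid(amplitude, delta, dt, smax)
    gap = max(1, int(round(Delta / dt)) - lobe.size)
    return np.concatenate([lobe, np.zeros(gap), lobe])


def _effective_diffusion(g: np.ndarray, dt: float) -> np.ndarray:
    """Negate samples after the midpoint (180° pulse) for b-value/spectrum."""
    eff = g.copy()
    mid = eff.size // 2
    eff[mid:] *= -1.0
    return eff


def b_value(g_eff: np.ndarray, dt: float, gamma: float = GAMMA_PROTON) -> float:
    """Numerical b-value of an effective 1-D diffusion waveform, s/mm²."""
    q = gamma * np.cumsum(g_eff) * dt            # rad/m
    b = np.sum(q * q) * dt                       # s/m² (rad² absorbed)
    return b * 1e-6                              # s/mm²


def _make_pgse(dt, gmax, smax, b=1000.0, delta=12e-3, Delta=20e-3,
               direction=(1.0, 0.0, 0.0), gamma=GAMMA_PROTON):
    """PGSE encode scaled to a requested b-value (s/mm²) along ``direction``.

    The trapezoid pair is built at the hardware amplitude limit, its maximum
    achievable b-value computed numerically, and the pair scaled down to the
    requested b; a request above the achievable maximum is infeasible.
    """
    full = _pgse_pair(gmax, delta, Delta, dt, smax)
    if b == 0:
        return GradientWaveform(np.zeros((3, full.size)), dt, kind="pgse",
                                gmax=gmax, smax=smax)
    b_max = b_value(_effective_diffusion(full, dt), dt, gamma)
    if b > b_max * (1 + 1e-9):
        raise InfeasibleWaveformError(
            f"b = {b} s/mm² exceeds the {b_max:.0f} s/mm² achievable with "
            f"delta = {delta * 1e3:.1f} ms, Delta = {Delta * 1e3:.1f} ms at "
            f"{gmax * 1e3:.1f} mT/m; increase delta/Delta")
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return GradientWaveform(np.outer(d, np.sqrt(b / b_max) * full), dt,
                            kind="pgse", gmax=gmax, smax=smax)


def _make_ogse(dt, gmax, smax, frequency=40.0, n_periods=4, amplitude=None,
               direction=(1.0, 0.0, 0.0), gamma=GAMMA_PROTON):
    """OGSE encode: two apodized cosine lobes oscillating at ``frequency``.

    Slew feasibility requires amplitude·2πf ≤ smax; the default amplitude is
    the smaller of the hardware limit and the slew-feasible amplitude.
    """
    w = 2 * np.pi * frequency
    a_slew = 0.9 * smax / w
    amp = min(gmax, a_slew) if amplitude is None else amplitude
    if amp * w > smax * (1 + 1e-9) or amp > gmax * (1 + 1e-9):
        raise InfeasibleWaveformError(
            f"OGSE amplitude {amp * 1e3:.1f} mT/m at {frequency} Hz violates limits")
    T = n_periods / frequency
    t = np.arange(int(round(T / dt))) * dt
    # raised-cosine ramps over half a period at each lobe end: smooth
    # start/stop without smearing the spectral peak away from `frequency`
    T_r = 0.5 / frequency
    apod = np.ones_like(t)
    head = t < T_r
    apod[head] = 0.5 * (1 - np.cos(np.pi * t[head] / T_r))
    tail = t > T - T_r
    apod[tail] = 0.5 * (1 - np.cos(np.pi * (T - t[tail]) / T_r))
    lobe = amp * np.sin(w * t) * apod
    gap = np.zeros(int(round(2e-3 / dt)))
    g1 = np.concatenate([lobe, gap, lobe])
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return GradientWaveform(np.outer(d, g1), dt, kind="ogse", gmax=gmax, smax=smax)


def _make_spiral(dt, gmax, smax, n_turns=16, fov=0.192, duration=10e-3,
                 gamma=GAMMA_PROTON):
    """Slew- and amplitude-limited Archimedean spiral readout (x/y axes).

    The trajectory is k(θ) = λ θ e^{iθ} with λ = n_turns / (2π · FOV/2).
    θ(t) is advanced by Euler integration at the largest angular velocity
    admitted by the amplitude limit (|dk/dθ| = λ√(1+θ²)) and an approximate
    slew limit (|d²k/dt²| ≈ λ θ (dθ/dt)² in the wound regime), with safety
    margins; residual discretization overshoot is clipped.
    """
    lam = n_turns / (2 * np.pi * (fov / 2.0))    # rad/m per rad of turn
    n = int(round(duration / dt))
    theta = np.empty(n)
    th = 0.0
    for i in range(n):
        theta[i] = th
        speed_amp = gamma * 0.85 * gmax / (lam * np.sqrt(1.0 + th * th))
        speed_slew = np.sqrt(gamma * 0.75 * smax / (lam * np.sqrt(1.0 + th * th)))
        th += min(speed_amp, speed_slew) * dt
    kx = lam * theta * np.cos(theta)
    ky = lam * theta * np.sin(theta)
    g = np.zeros((3, n))
    g[0, 1:] = np.diff(kx) / (gamma * dt)
    g[1, 1:] = np.diff(ky) / (gamma * dt)
    np.clip(g, -0.98 * gmax, 0.98 * gmax, out=g)
    dgd = np.diff(g, axis=1)
    np.clip(dgd, -0.98 * smax * dt, 0.98 * smax * dt, out=dgd)
    g[:, 1:] = g[:, :1] + np.cumsum(dgd, axis=1)
    np.clip(g, -gmax, gmax, out=g)
    return GradientWaveform(g, dt, kind="spiral", gmax=gmax, smax=smax)


def _make_epi(dt, gmax, smax, n_lines=24, read_amplitude=None, flat_time=0.25e-3,
              blip_area_frac=0.05):
    """EPI readout: alternating read trapezoids with phase blips."""
    amp = 0.8 * gmax if read_amplitude is None else read_amplitude
    if amp > gmax * (1 + 1e-9):
        raise InfeasibleWaveformError("EPI read amplitude exceeds gradient limit")
    lobe = _trapezoid(amp, flat_time, dt, smax)
    blip = _trapezoid(0.5 * gmax, blip_area_frac * flat_time, dt, smax)
    segs_x, segs_y = [], []
    for i in range(n_lines):
        s = 1.0 if i % 2 == 0 else -1.0
        segs_x.append(s * lobe)
        segs_y.append(np.zeros(lobe.size))
        if i < n_lines - 1:
            segs_x.append(np.zeros(blip.size))
            segs_y.append(blip)
    gx = np.concatenate(segs_x)
    gy = np.concatenate(segs_y)
    g = np.zeros((3, gx.size))
    g[0], g[1] = gx, gy
    return GradientWaveform(g, dt, kind="epi", gmax=gmax, smax=smax)


def _make_chirp(dt, gmax, smax, f0=10.0, f1=600.0, duration=30e-3,
                amplitude=None, axis=0):
    """Linear frequency sweep for broadband eddy-current calibration."""
    a_slew = 0.9 * smax / (2 * np.pi * f1)
    amp = min(0.9 * gmax, a_slew) if amplitude is None else amplitude
    if amp > gmax * (1 + 1e-9):
        raise InfeasibleWaveformError("chirp amplitude exceeds gradient limit")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t**2 / duration)
    wav = amp * np.sin(phase) * np.sin(np.pi * t / duration)
    g = np.zeros((3, n))
    g[axis] = wav
    return GradientWaveform(g, dt, kind="chirp", gmax=gmax, smax=smax)


_WAVEFORM_MAKERS = {
    "pgse": _make_pgse,
    "ogse": _make_ogse,
    "spiral": _make_spiral,
    "epi": _make_epi,
    "chirp": _make_chirp,
}


def make_waveform(kind: str, dt: float = DEFAULT_DT, gmax: float = DEFAULT_GMAX,
                  smax: float = DEFAULT_SMAX, **params) -> GradientWaveform:
    """Construct a named gradient waveform.

    ``kind`` is one of ``spiral | epi | pgse | ogse | chirp``.  All waveforms
    respect the ``gmax``/``smax`` hardware limits or raise
    :class:`InfeasibleWaveformError`.
    """
    try:
        maker = _WAVEFORM_MAKERS[kind]
    except KeyError:
        raise ValueError(f"unknown waveform kind {kind!r}; "
                         f"choose from {sorted(_WAVEFORM_MAKERS)}") from None
    return maker(dt, gmax, smax, **params)


# ---------------------------------------------------------------------------
# Eddy-current ground truth
# ---------------------------------------------------------------------------

def _eddy_k(g_axis: np.ndarray, dt: float, amplitude: float, tau: float,
            gamma: float) -> np.ndarray:
    """Exact k-response of one LTI eddy mode to a piecewise-constant gradient.

    For a gradient increment Δg at sample j the induced field is
    −A Δg e^{−(t−t_j)/τ} and its accrued phase coefficient
    −γ A Δg τ (1 − e^{−(t−t_j)/τ}); summing over increments is a discrete
    convolution with the closed-form kernel, exact for raster waveforms.
    """
    n = g_axis.size
    dg = np.diff(g_axis, prepend=0.0)
    tt = np.arange(n) * dt
    kernel = -gamma * amplitude * tau * (1.0 - np.exp(-tt / tau))
    from scipy.signal import fftconvolve
    return fftconvolve(dg, kernel)[:n]


def simulate_k_true(scene: EddyGradientScene, max_order: int) -> KCoefficients:
    """Ground-truth k-coefficient time-courses for a scene.

    The nominal gradient contributes ``γ ∫ g dt`` to the three first-order
    rows; every eddy mode adds its exact LTI response to its basis row
    (first-order eddy modes superpose onto the nominal terms).
    """
    indexing = HarmonicIndexing(max_order)
    wf = scene.waveform
    nt = wf.n_samples
    k = np.zeros((indexing.count, nt))
    lin = indexing.linear_indices
    for ax, name in enumerate(("x", "y", "z")):
        k[lin[name]] = scene.gamma * np.cumsum(wf.g[ax]) * wf.dt
    for mode in scene.modes:
        if mode.basis_index >= indexing.count:
            raise ValueError(
                f"mode basis_index {mode.basis_index} outside order-{max_order} basis")
        k[mode.basis_index] += _eddy_k(wf.g[mode.source_axis], wf.dt,
                                       mode.amplitude, mode.tau, scene.gamma)
    return KCoefficients(k=k, indexing=indexing, time=wf.time)


# ---------------------------------------------------------------------------
# Probe layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeLayoutSpec:
    """Multi-position calibration layout: a 16-probe shell replicated over
    z-shifts and z-rotations, then filtered by distance from isocenter."""

    base_positions: np.ndarray = None  # type: ignore[assignment]
    n_z_shifts: int = 3
    z_spacing: float = 0.05
    n_rotations: int = 3
    r_max: float = 0.16
    axis_max: float = 0.14

    def __post_init__(self):
        if self.base_positions is None:
            object.__setattr__(self, "base_positions", _default_probe_shell())
        else:
            pos = np.atleast_2d(np.asarray(self.base_positions, float))
            if pos.shape[1] != 3:
                raise ValueError("base_positions must be (N, 3)")
            object.__setattr__(self, "base_positions", pos)
        if self.n_z_shifts < 1 or self.n_rotations < 1:
            raise ValueError("n_z_shifts and n_rotations must be >= 1")


def _default_probe_shell(n: int = 16, r_min: float = 0.119, r_max: float = 0.149) -> np.ndarray:
    """Deterministic 16-probe shell: golden-angle azimuths, radii cycling
    through [r_min, r_max] (mean ≈ 13.5 cm, matching a head-coil mount)."""
    i = np.arange(n)
    zf = np.linspace(-0.95, 0.95, n)             # polar spread
    phi = i * np.pi * (3.0 - np.sqrt(5.0))       # golden angle
    radii = r_min + (r_max - r_min) * ((i * 7) % n) / (n - 1)
    st = np.sqrt(1.0 - zf**2)
    return np.column_stack([radii * st * np.cos(phi),
                            radii * st * np.sin(phi),
                            radii * zf])


def _passes_filters(pos: np.ndarray, r_max: float, axis_max: float) -> np.ndarray:
    return (np.linalg.norm(pos, axis=1) <= r_max) & np.all(np.abs(pos) <= axis_max, axis=1)


def build_probe_array(spec: ProbeLayoutSpec = ProbeLayoutSpec()
                      ) -> tuple[ProbeArray, ProbeArray]:
    """Build the calibration and single-position probe arrays.

    The calibration array is the union of the base shell under every
    z-shift × rotation combination, keeping only probes within ``r_max`` of
    isocenter and within ``axis_max`` on each axis (avoiding regions of
    gradient nonlinearity).  Returns ``(calibration_array, base_array)``.
    """
    base = spec.base_positions
    # one-sided shifts: the probe mount can only translate out of the bore
    shifts = np.arange(spec.n_z_shifts) * spec.z_spacing
    angles = 2 * np.pi * np.arange(spec.n_rotations) / spec.n_rotations
    candidates = []
    for dz in shifts:
        for a in angles:
            ca, sa = np.cos(a), np.sin(a)
            rot = base @ np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
            rot = rot + np.array([0.0, 0.0, dz])
            candidates.append(rot)
    cand = np.concatenate(candidates, axis=0)
    keep = _passes_filters(cand, spec.r_max, spec.axis_max)
    if not np.any(keep):
        raise ValueError("all candidate probes removed by distance filters")
    return ProbeArray(cand[keep]), ProbeArray(base)


# ---------------------------------------------------------------------------
# Monitoring data
# ---------------------------------------------------------------------------

def generate_monitoring_data(scene: EddyGradientScene, probes: ProbeArray,
                             max_order: int, seed: int,
                             B0: float | None = None,
                             ) -> tuple[PhaseData, KCoefficients, "ProbingMatrix"]:
    """Simulate noisy probe phase for a scene: ``phi = P k_true + ε``.

    ``ε`` is iid Gaussian with the scene's ``noise_sd`` (rad), seeded
    reproducibly.  When ``B0`` is given, the concomitant (Maxwell) phase of
    the nominal gradient waveform is added with the same formula the fitting
    module uses for correction.
    """
    rng = np.random.default_rng(seed)
    P = evaluate_basis(probes, max_order)
    k_true = simulate_k_true(scene, max_order)
    phi = P.values @ k_true.k
    if B0 is not None:
        phi = phi + concomitant_phase(probes.positions, scene.waveform.g,
                                      k_true.time, B0, gamma=scene.gamma)
    if scene.noise_sd > 0:
        phi = phi + rng.normal(0.0, scene.noise_sd, size=phi.shape)
    phase = PhaseData(phi=phi, time=k_true.time)
    return phase, k_true, P


# ---------------------------------------------------------------------------
# Direction sets and probe subsets (electrostatic repulsion)
# ---------------------------------------------------------------------------

def repulsion_energy(points: np.ndarray, antipodal: bool = True) -> float:
    """Coulomb-style 1/distance energy of a point set on the unit sphere.

    With ``antipodal`` each point also repels the mirror images (−p_j), the
    standard criterion for diffusion direction sets where ±g are equivalent.
    """
    pts = np.asarray(points, float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    iu = np.triu_indices(len(pts), 1)
    e = np.sum(1.0 / d[iu])
    if antipodal:
        da = np.linalg.norm(pts[:, None, :] + pts[None, :, :], axis=-1)
        e += np.sum(1.0 / da[iu]) + np.sum(1.0 / np.diag(da))
    return float(e)


def uniform_directions(n: int, seed: int, iterations: int = 1000,
                       antipodal: bool = True) -> np.ndarray:
    """Uniformly spread unit vectors by electrostatic-repulsion descent.

    Gradient descent on the 1/distance energy (with antipodal symmetry for
    diffusion schemes), renormalizing to the sphere each step; fixed
    iteration cap, deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.05
    e_prev = repulsion_energy(pts, antipodal)
    for _ in range(iterations):
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        force = np.sum(diff / dist[..., None] ** 3, axis=1)
        if antipodal:
            diff_a = pts[:, None, :] + pts[None, :, :]
            dist_a = np.linalg.norm(diff_a, axis=-1)
            force += np.sum(diff_a / dist_a[..., None] ** 3, axis=1)
        cand = pts + step * force
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        e_new = repulsion_energy(cand, antipodal)
        if e_new < e_prev:
            pts, e_prev = cand, e_new
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return pts


def select_probe_subset(probes: ProbeArray, n: int, iterations: int = 200) -> np.ndarray:
    """Indices of an ``n``-probe subset maximizing mutual spread.

    Greedy farthest-point seeding followed by exchange passes that maximize
    the pairwise 1/distance repulsion criterion; deterministic.
    """
    pos = probes.positions
    m = pos.shape[0]
    if not (1 <= n <= m):
        raise ValueError(f"subset size must be in 1..{m}")
    if n == m:
        return np.arange(m)
    d2 = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    sel = [int(np.argmax(np.linalg.norm(pos, axis=1)))]
    while len(sel) < n:
        mind = d2[:, sel].min(axis=1)
        mind[sel] = -np.inf
        sel.append(int(np.argmax(mind)))
    sel = np.array(sorted(sel))

    def energy(idx):
        sub = d2[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        return np.sum(1.0 / np.maximum(sub[iu], 1e-9))

    e = energy(sel)
    rest = np.setdiff1d(np.arange(m), sel)
    for _ in range(iterations):
        improved = False
        for i in range(len(sel)):
            for j in range(len(rest)):
                trial = sel.copy()
                trial[i] = rest[j]
                e_t = energy(trial)
                if e_t < e:
                    rest[j] = sel[i]
                    sel = np.sort(trial)
                    e = e_t
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return sel
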