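"""Weighted least-squares k-coefficient estimation from probe phase.

The forward model is ``phi = P @ k`` (optionally ``phi = W P k`` with a
per-probe weighting ``W``); fitting inverts it with the Moore–Penrose
pseudoinverse, equivalently the weighted normal equations
``k = (PᵀW²P)⁻¹ PᵀW² phi``.  The module also implements the iterative
concomitant-field (Maxwell term) refit: the lowest-order concomitant phase is
predicted from the fitted first-order k-coefficients, subtracted from the
probe phase, and the fit repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonics import HarmonicIndexing, ProbeArray, ProbingMatrix

__all__ = [
    "GAMMA_PROTON",
    "PhaseData",
    "KCoefficients",
    "IllPosedFitError",
    "synthesize_phase",
    "fit_k",
    "concomitant_field",
    "concomitant_phase",
    "concomitant_refit",
]

#: Proton gyromagnetic ratio, rad/s/T.
GAMMA_PROTON = 267.522187e6

#: Condition-number threshold above which a fit is declared ill-posed.
COND_LIMIT = 1e10


class IllPosedFitError(ValueError):
    """Raised when the (weighted) probing matrix cannot support a fit."""


@dataclass(frozen=True)
class PhaseData:
    """Probe phase time-series: ``phi`` is Np × Nt in radians."""

    phi: np.ndarray
    time: np.ndarray
    segment_labels: np.ndarray | None = None

    def __post_init__(self):
        phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        t = np.asarray(self.time, dtype=float).ravel()
        if phi.shape[1] != t.shape[0]:
            raise ValueError("time axis length must match phi columns")
        if not np.all(np.isfinite(phi)):
            raise ValueError("phase must be finite")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "time", t)
        labels = self.segment_labels
        if labels is None:
            labels = np.zeros(t.shape[0], dtype=int)
        else:
            labels = np.asarray(labels).ravel()
            if labels.shape[0] != t.shape[0]:
                raise ValueError("segment_labels length must match time axis")
        object.__setattr__(self, "segment_labels", labels)

    @property
    def n_probes(self) -> int:
        return self.phi.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phi.shape[1]


@dataclass(frozen=True)
class KCoefficients:
    """Basis-expansion coefficient time-courses.

    Row ``i`` corresponds to basis function ``indexing.index_map[i]`` and has
    units rad/m^{l_i}.
    """

    k: np.ndarray
    indexing: HarmonicIndexing
    time: np.ndarray
    segment_labels: np.ndarray | None = None

    def __post_init__(self):
        k = np.atleast_2d(np.asarray(self.k, dtype=float))
        if k.shape[0] != self.indexing.count:
            raise ValueError(
                f"k has {k.shape[0]} rows but indexing expects {self.indexing.count}")
        if not np.all(np.isfinite(k)):
            raise ValueError("k-coefficients must be finite")
        t = np.asarray(self.time, dtype=float).ravel()
        if t.shape[0] != k.shape[1]:
            raise ValueError("time axis length must match k columns")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "time", t)
        labels = self.segment_labels
        if labels is None:
            labels = np.zeros(t.shape[0], dtype=int)
        else:
            labels = np.asarray(labels).ravel()
            if labels.shape[0] != t.shape[0]:
                raise ValueError("segment_labels length must match time axis")
        object.__setattr__(self, "segment_labels", labels)

    @property
    def n_basis(self) -> int:
        return self.k.shape[0]

    @property
    def n_samples(self) -> int:
        return self.k.shape[1]


def synthesize_phase(P: ProbingMatrix, k: KCoefficients) -> PhaseData:
    """Forward model ``phi = P @ k`` (no noise)."""
    if P.n_basis != k.n_basis:
        raise ValueError(
            f"probing matrix has {P.n_basis} columns, k has {k.n_basis} rows")
    return PhaseData(phi=P.values @ k.k, time=k.time, segment_labels=k.segment_labels)


def _weighted_design(P: ProbingMatrix, weights) -> tuple[np.ndarray, np.ndarray]:
    w = np.ones(P.n_probes) if weights is None else np.asarray(weights, float).ravel()
    if w.shape[0] != P.n_probes:
        raise ValueError("weights length must match probe count")
    if not np.all(w > 0):
        raise ValueError("weights must be strictly positive")
    return P.values * w[:, None], w


def _check_conditioning(A: np.ndarray, indexing: HarmonicIndexing) -> None:
    # Column-equilibrate before conditioning: harmonic columns span many
    # decades purely from units (m^l), which is not a true deficiency.
    scale = np.linalg.norm(A, axis=0)
    bad_cols = np.where(scale == 0)[0]
    if bad_cols.size == 0:
        As = A / scale
        sv = np.linalg.svd(As, compute_uv=False)
        if sv[-1] > 0 and sv[0] / sv[-1] <= COND_LIMIT:
            return
        # identify columns aligned with the (near-)null space
        _, _, Vt = np.linalg.svd(As)
        null = Vt[sv.size - 1:]
        bad_cols = np.argsort(-np.abs(null).sum(axis=0))[:3]
    names = [indexing.index_map[j] for j in sorted(set(int(j) for j in bad_cols))]
    raise IllPosedFitError(
        "probing matrix is rank deficient or too ill-conditioned to fit; "
        f"deficient columns (l, m): {names}")


def fit_k(phase: PhaseData, P: ProbingMatrix, weights=None) -> KCoefficients:
    """Least-squares fit of k-coefficients to probe phase.

    With ``weights`` (per-probe, the diagonal of W) this solves
    ``min ||W (phi − P k)||``; the solution equals ``(PᵀW²P)⁻¹ PᵀW² phi``.
    Without weights it is the plain pseudoinverse solution.

    Raises
    ------
    IllPosedFitError
        If there are fewer probes than basis functions, or the (weighted)
        probing matrix is numerically rank deficient.
    """
    if phase.n_probes != P.n_probes:
        raise ValueError("phase and probing matrix probe counts differ")
    if P.n_probes < P.n_basis:
        raise IllPosedFitError(
            f"{P.n_probes} probes cannot determine {P.n_basis} basis functions; "
            f"reduce the order or supply at least {P.n_basis} probes")
    A, w = _weighted_design(P, weights)
    _check_conditioning(A, P.indexing)
    k, *_ = np.linalg.lstsq(A, phase.phi * w[:, None], rcond=None)
    return KCoefficients(k=k, indexing=P.indexing, time=phase.time,
                         segment_labels=phase.segment_labels)


def concomitant_field(positions: np.ndarray, g: np.ndarray, B0: float) -> np.ndarray:
    """Lowest-order concomitant (Maxwell) field at each position.

    For a symmetric gradient coil the leading concomitant term is

        B_c = (1/(2 B0)) (Gx² z² + Gy² z² + Gz² (x² + y²)/4
                          − Gx Gz x z − Gy Gz y z)

    Parameters
    ----------
    positions : (Np, 3) meters
    g : (3, Nt) gradient waveforms, T/m
    B0 : main field, tesla

    Returns
    -------
    (Np, Nt) field in tesla.
    """
    if B0 <= 0:
        raise ValueError("B0 must be positive")
    x, y, z = positions[:, 0:1], positions[:, 1:2], positions[:, 2:3]
    gx, gy, gz = g[0][None, :], g[1][None, :], g[2][None, :]
    return (gx**2 * z**2 + gy**2 * z**2 + gz**2 * (x**2 + y**2) / 4.0
            - gx * gz * x * z - gy * gz * y * z) / (2.0 * B0)


def _segment_slices(labels: np.ndarray):
    # contiguous runs of equal segment label
    change = np.flatnonzero(np.diff(labels)) + 1
    edges = np.concatenate(([0], change, [labels.size]))
    for a, b in zip(edges[:-1], edges[1:]):
        yield slice(a, b)


def concomitant_phase(positions: np.ndarray, g: np.ndarray, time: np.ndarray,
                      B0: float, gamma: float = GAMMA_PROTON,
                      segment_labels: np.ndarray | None = None) -> np.ndarray:
    """Accumulated concomitant phase ``gamma * ∫ B_c dt`` per probe (rad).

    Integration restarts at each segment boundary (each volume/readout starts
    from freshly excited probes with zero accrued phase).
    """
    bc = concomitant_field(positions, g, B0)
    phase = np.empty_like(bc)
    labels = np.zeros(time.size, int) if segment_labels is None else segment_labels
    for sl in _segment_slices(np.asarray(labels)):
        t = time[sl]
        seg = bc[:, sl]
        dt = np.diff(t, prepend=t[0])
        dt[0] = dt[1] if dt.size > 1 else 0.0
        phase[:, sl] = gamma * np.cumsum(seg * dt[None, :], axis=1)
    return phase


def _gradient_from_k(k: KCoefficients, gamma: float) -> np.ndarray:
    """Recover (3, Nt) gradient waveforms from first-order k rows.

    k_1(t) = gamma * ∫ G dt  =>  G = (dk_1/dt) / gamma, per segment.
    """
    lin = k.indexing.linear_indices
    g = np.empty((3, k.n_samples))
    for ax, name in enumerate(("x", "y", "z")):
        row = k.k[lin[name]]
        for sl in _segment_slices(k.segment_labels):
            t = k.time[sl]
            if t.size < 2:
                g[ax, sl] = 0.0
                continue
            g[ax, sl] = np.gradient(row[sl], t) / gamma
    return g


def concomitant_refit(phase: PhaseData, P: ProbingMatrix, B0: float,
                      iterations: int = 2, model=None, weights=None,
                      gamma: float = GAMMA_PROTON, tol: float = 1e-6,
                      positions: np.ndarray | None = None) -> KCoefficients:
    """Iteratively remove concomitant-field phase and refit k-coefficients.

    Each iteration: fit (compressed when ``model`` is given, conventional
    otherwise) → differentiate the first-order k rows to recover the gradient
    waveforms → evaluate the lowest-order concomitant field at the probe
    positions → subtract the accrued concomitant phase from ``phi`` → refit.
    Stops after ``iterations`` rounds or when max |Δk| / max |k| < ``tol``.

    ``positions`` must be supplied when the probing matrix alone is available;
    by default they are reconstructed from P's first-order columns.
    """
    if B0 <= 0:
        raise ValueError("B0 must be positive")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if positions is None:
        lin = P.indexing.linear_indices
        positions = np.column_stack([P.values[:, lin[a]] for a in ("x", "y", "z")])

    def _fit(ph: PhaseData) -> KCoefficients:
        if model is not None:
            from .compression import fit_compressed
            _, k = fit_compressed(ph, P, model, weights=weights)
            return k
        return fit_k(ph, P, weights=weights)

    k = _fit(phase)
    for _ in range(iterations):
        g = _gradient_from_k(k, gamma)
        phi_c = concomitant_phase(positions, g, phase.time, B0, gamma=gamma,
                                  segment_labels=phase.segment_labels)
        corrected = PhaseData(phi=phase.phi - phi_c, time=phase.time,
                              segment_labels=phase.segment_labels)
        k_new = _fit(corrected)
        denom = np.max(np.abs(k_new.k))
        if denom > 0 and np.max(np.abs(k_new.k - k.k)) / denom < tol:
            k = k_new
            break
        k = k_new
    return k
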