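"""Data-driven compression of high-order solid-harmonic basis functions.

A multi-position calibration scan yields ground-truth k-coefficient
time-courses ``k_calib``.  Because gradient systems are built to produce
linear fields, the degree-0/1 terms (first four rows) are kept as-is; the
remaining high-order rows are compressed with an economic SVD of the
order-weighted block::

    Γ_high k_calib_high = U Σ Vᵀ,       Γ_high,ii = base**l_i

Keeping the leading ``L`` left singular vectors gives ``C_high`` with
orthonormal columns, and the block matrices

    Γ = diag(I₄, Γ_high),   C = [[I₄, 0], [0, C_high]]

define the compression ``k̂ = Cᵀ Γ k``, its (approximate) inverse
``k ≈ Γ⁻¹ C k̂``, and the compressed probing matrix ``P̂ = P Γ⁻¹ C`` used for
fitting with few probes: with ``L + 4`` unknowns instead of ``(max_order+1)²``
a 16-probe array can fit 5th-order dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .harmonics import HarmonicIndexing, ProbingMatrix, order_weights
from .fitting import (IllPosedFitError, KCoefficients, PhaseData,
                      _check_conditioning)

__all__ = [
    "CompressionModel",
    "build_compression",
    "compress_k",
    "decompress_k",
    "compressed_probing",
    "fit_compressed",
]


@dataclass(frozen=True)
class CompressionModel:
    """Learned low-rank basis for high-order field dynamics.

    Attributes
    ----------
    C_high : (Nb − 4, L) orthonormal columns (leading left singular vectors).
    singular_values : full singular spectrum of the weighted high-order block,
        kept for diagnostics (scree inspection, threshold selection).
    gamma_base : base of the order weighting Γ_ii = base**l_i.
    """

    indexing: HarmonicIndexing
    C_high: np.ndarray
    singular_values: np.ndarray
    gamma_base: float = 0.1

    def __post_init__(self):
        nb = self.indexing.count
        C_high = np.atleast_2d(np.asarray(self.C_high, dtype=float))
        if C_high.shape[0] != nb - 4:
            raise ValueError(f"C_high must have {nb - 4} rows, got {C_high.shape[0]}")
        if not (1 <= C_high.shape[1] <= nb - 4):
            raise ValueError("retained count L must satisfy 1 <= L <= Nb - 4")
        object.__setattr__(self, "C_high", C_high)
        sv = np.asarray(self.singular_values, dtype=float).ravel()
        if np.any(np.diff(sv) > 1e-12 * max(sv[0], 1.0) if sv.size else False):
            raise ValueError("singular values must be non-increasing")
        object.__setattr__(self, "singular_values", sv)

    @property
    def max_order(self) -> int:
        return self.indexing.max_order

    @property
    def n_basis(self) -> int:
        return self.indexing.count

    @property
    def L(self) -> int:
        """Number of retained singular vectors."""
        return self.C_high.shape[1]

    @property
    def n_compressed(self) -> int:
        """Total compressed coefficient count, L + 4."""
        return self.L + 4

    @property
    def gamma(self) -> np.ndarray:
        """Diagonal of Γ (length Nb): identity low block, base**l high block."""
        return order_weights(self.max_order, base=self.gamma_base, protect_low=True)

    @property
    def Gamma(self) -> np.ndarray:
        return np.diag(self.gamma)

    @property
    def C(self) -> np.ndarray:
        """Nb × (L + 4) block compression matrix [[I₄, 0], [0, C_high]]."""
        nb = self.n_basis
        C = np.zeros((nb, self.L + 4))
        C[:4, :4] = np.eye(4)
        C[4:, 4:] = self.C_high
        return C

    def truncated(self, L: int) -> "CompressionModel":
        """Same calibration, fewer retained singular vectors (L ≤ current L)."""
        if not (1 <= L <= self.L):
            raise ValueError(f"L must be in 1..{self.L}")
        return CompressionModel(indexing=self.indexing, C_high=self.C_high[:, :L],
                                singular_values=self.singular_values,
                                gamma_base=self.gamma_base)


def build_compression(k_calib: KCoefficients, L, gamma_base: float = 0.1,
                      ) -> CompressionModel:
    """Learn a compression matrix from calibration k-coefficients.

    Parameters
    ----------
    k_calib
        Ground-truth k-coefficient time-courses from a (multi-position)
        calibration fit; multiple scans may be concatenated along time
        beforehand.  Rows 0–3 (degrees 0 and 1) are excluded from the SVD.
    L
        Number of singular vectors to retain.  An ``int`` keeps exactly that
        many; a ``float`` in (0, 1) is a relative singular-value threshold
        (keep all σ_i ≥ L·σ_1).
    gamma_base
        Base of the order weighting applied before the SVD (default 0.1, i.e.
        equalize degrees over a 1-dm radius).

    Notes
    -----
    A deterministic sign convention is applied: each retained singular vector
    is flipped so its largest-magnitude entry is positive.  If ``L`` exceeds
    the numerical rank of the calibration block it is clamped with a warning,
    as is a calibration shorter than ``Nb − 4`` samples.
    """
    indexing = k_calib.indexing
    nb = indexing.count
    if nb < 5:
        raise ValueError("calibration must include orders >= 2 (max_order >= 2)")
    n_high = nb - 4
    if k_calib.n_samples < n_high:
        warnings.warn(
            f"calibration has {k_calib.n_samples} samples < {n_high} high-order "
            "basis functions; the learned model is rank-limited", stacklevel=2)

    gamma_high = gamma_base ** indexing.orders[4:].astype(float)
    A = gamma_high[:, None] * k_calib.k[4:]
    U, sv, _ = np.linalg.svd(A, full_matrices=False)

    if isinstance(L, float) and 0 < L < 1:
        L_eff = max(1, int(np.sum(sv >= L * sv[0]))) if sv.size else 1
    else:
        L_eff = int(L)
    if not (1 <= L_eff <= n_high):
        raise ValueError(f"L must be in 1..{n_high}, got {L_eff}")
    tol = sv[0] * max(A.shape) * np.finfo(float).eps if sv.size else 0.0
    rank = int(np.sum(sv > tol))
    if L_eff > max(rank, 1):
        warnings.warn(
            f"requested L={L_eff} exceeds numerical rank {rank}; clamping",
            stacklevel=2)
        L_eff = max(rank, 1)

    C_high = U[:, :L_eff].copy()
    # deterministic sign: largest-magnitude entry of each column positive
    piv = np.argmax(np.abs(C_high), axis=0)
    signs = np.sign(C_high[piv, np.arange(L_eff)])
    signs[signs == 0] = 1.0
    C_high *= signs[None, :]

    return CompressionModel(indexing=indexing, C_high=C_high,
                            singular_values=sv, gamma_base=gamma_base)


def compress_k(k: KCoefficients, model: CompressionModel) -> np.ndarray:
    """Project k-coefficients into the compressed basis: ``k̂ = Cᵀ Γ k``.

    Rows 0–3 of the result equal rows 0–3 of ``k`` (identity block); the
    remaining ``L`` rows are Γ-weighted projections onto the retained singular
    vectors.  Returns an ``(L + 4) × Nt`` array.
    """
    if k.n_basis != model.n_basis:
        raise ValueError(
            f"k has {k.n_basis} rows but model expects {model.n_basis}")
    return model.C.T @ (model.gamma[:, None] * k.k)


def decompress_k(k_hat: np.ndarray, model: CompressionModel,
                 time=None, segment_labels=None) -> KCoefficients:
    """Map compressed coefficients back to solid-harmonic form: ``k ≈ Γ⁻¹ C k̂``.

    Exact on the retained subspace; elsewhere the round trip
    ``decompress(compress(k))`` is the Γ-metric orthogonal projection onto it.
    """
    k_hat = np.atleast_2d(np.asarray(k_hat, dtype=float))
    if k_hat.shape[0] != model.n_compressed:
        raise ValueError(
            f"k_hat has {k_hat.shape[0]} rows but model expects {model.n_compressed}")
    k = (model.C @ k_hat) / model.gamma[:, None]
    if time is None:
        time = np.arange(k.shape[1], dtype=float)
    return KCoefficients(k=k, indexing=model.indexing, time=time,
                         segment_labels=segment_labels)


def compressed_probing(P: ProbingMatrix, model: CompressionModel) -> np.ndarray:
    """Compressed probing matrix ``P̂ = P Γ⁻¹ C``, shape Np × (L + 4).

    Its leading four columns equal P's (degree-0/1 functions pass through
    unchanged); the rest evaluate the learned compressed basis functions at
    the probe positions.
    """
    if P.indexing.max_order != model.max_order:
        raise ValueError(
            f"probing matrix order {P.indexing.max_order} != model order "
            f"{model.max_order}")
    return (P.values / model.gamma[None, :]) @ model.C


def fit_compressed(phase: PhaseData, P: ProbingMatrix, model: CompressionModel,
                   weights=None) -> tuple[np.ndarray, KCoefficients]:
    """Weighted least-squares fit in the compressed basis.

    Solves ``min ||W (phi − P̂ k̂)||`` with ``P̂ = P Γ⁻¹ C`` and returns both
    the compressed solution ``k̂`` and its decompressed solid-harmonic form
    for downstream use (e.g. expanded-encoding reconstruction).
    """
    n_unknown = model.n_compressed
    if phase.n_probes != P.n_probes:
        raise ValueError("phase and probing matrix probe counts differ")
    if P.n_probes < n_unknown:
        raise IllPosedFitError(
            f"{P.n_probes} probes cannot determine {n_unknown} compressed "
            f"coefficients; with 4 uncompressed low-order terms the maximum "
            f"admissible L here is {P.n_probes - 4}")
    P_hat = compressed_probing(P, model)
    w = np.ones(P.n_probes) if weights is None else np.asarray(weights, float).ravel()
    A = P_hat * w[:, None]
    _check_conditioning(A, P.indexing)
    k_hat, *_ = np.linalg.lstsq(A, phase.phi * w[:, None], rcond=None)
    k = decompress_k(k_hat, model, time=phase.time,
                     segment_labels=phase.segment_labels)
    return k_hat, k
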