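"""Real solid-harmonic basis evaluation and probing-matrix construction.

Field-probe phase is modelled as a spatial expansion in regular (interior)
solid harmonics: polynomial solutions of Laplace's equation whose degree-``l``
terms scale as ``r**l``.  Evaluating the first ``(max_order + 1)**2`` of them
at the probe positions yields the *probing matrix* ``P`` that maps
k-coefficient time-courses (units rad/m^l) to probe phases (rad).

Convention
----------
The package uses unnormalized tesseral regular solid harmonics

    S_l^m(r) = r^l P_l^|m|(cos θ) · { cos(|m| φ)  for m ≥ 0
                                    { sin(|m| φ)  for m < 0

with associated Legendre functions *without* the Condon–Shortley phase,
ordered by ascending degree ``l`` and, within each degree, by ascending
``m = −l .. +l``.  The first four basis functions are therefore
``1, y, z, x``.  The low-degree polynomials are::

    l=0:  1
    l=1:  y, z, x
    l=2:  6xy, 3yz, (2z² − x² − y²)/2, 3xz, 3(x² − y²)

Any self-consistent real solid-harmonic convention is equivalent for fitting
as long as simulation and fitting share it; this one is fixed package-wide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HarmonicIndexing",
    "ProbeArray",
    "ProbingMatrix",
    "count_basis",
    "evaluate_basis",
    "order_weights",
]


def count_basis(max_order: int) -> int:
    """Number of real solid-harmonic basis functions up to ``max_order``.

    Degrees ``l = 0 .. max_order`` contribute ``2l + 1`` functions each, for a
    total of ``(max_order + 1)**2`` — e.g. 16 functions at third order.
    """
    if max_order < 0:
        raise ValueError(f"max_order must be >= 0, got {max_order}")
    return (int(max_order) + 1) ** 2


@dataclass(frozen=True)
class HarmonicIndexing:
    """Row/column bookkeeping for a solid-harmonic expansion.

    ``index_map[i]`` is the ``(l, m)`` pair of basis function ``i``; rows are
    sorted by ascending ``l`` then ascending ``m``.
    """

    max_order: int
    index_map: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.max_order < 0:
            raise ValueError("max_order must be >= 0")
        pairs = tuple(
            (l, m) for l in range(self.max_order + 1) for m in range(-l, l + 1)
        )
        object.__setattr__(self, "index_map", pairs)

    @property
    def count(self) -> int:
        return (self.max_order + 1) ** 2

    @property
    def orders(self) -> np.ndarray:
        """Degree ``l_i`` of each basis function, shape ``(count,)``."""
        return np.array([l for l, _ in self.index_map], dtype=int)

    def index_of(self, l: int, m: int) -> int:
        """Flat index of the ``(l, m)`` basis function."""
        if not (0 <= l <= self.max_order and -l <= m <= l):
            raise ValueError(f"(l={l}, m={m}) outside indexing of order {self.max_order}")
        return l * l + (m + l)

    @property
    def linear_indices(self) -> dict:
        """Map axis name -> row index of the matching first-order function."""
        return {"x": self.index_of(1, 1), "y": self.index_of(1, -1), "z": self.index_of(1, 0)}


@dataclass(frozen=True)
class ProbeArray:
    """Probe positions (meters, scanner frame, origin at isocenter) with
    optional per-probe fit weights (diagonal of W)."""

    positions: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError(f"positions must be (Np, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("probe positions must be finite")
        object.__setattr__(self, "positions", pos)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).ravel()
            if w.shape[0] != pos.shape[0]:
                raise ValueError("weights length must equal number of probes")
            if not (np.all(np.isfinite(w)) and np.all(w > 0)):
                raise ValueError("weights must be finite and strictly positive")
            object.__setattr__(self, "weights", w)

    @property
    def n_probes(self) -> int:
        return self.positions.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    def subset(self, indices) -> "ProbeArray":
        idx = np.asarray(indices, dtype=int)
        w = self.weights[idx] if self.weights is not None else None
        return ProbeArray(self.positions[idx], w)


@dataclass(frozen=True)
class ProbingMatrix:
    """Np × Nb matrix of solid-harmonic values at the probe positions."""

    values: np.ndarray
    indexing: HarmonicIndexing
    positions_hash: str = ""

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]


def _positions_hash(positions: np.ndarray) -> str:
    h = hashlib.sha256(np.ascontiguousarray(positions, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _solid_harmonic_table(xyz: np.ndarray, max_order: int) -> np.ndarray:
    """Evaluate all S_l^m at each point via the stable Hobson-type recursion.

    Diagonal:  S_{m,m}^c + i S_{m,m}^s = (2m−1)!! (x + iy)^m
    Step up:   S_{m+1,m} = (2m+1) z S_{m,m}
    Vertical:  (l−m) S_{l,m} = (2l−1) z S_{l−1,m} − (l−1+m) r² S_{l−2,m}
    """
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    r2 = x * x + y * y + z * z
    n = xyz.shape[0]
    # c[l][m], s[l][m] for m >= 0
    c = [[None] * (l + 1) for l in range(max_order + 1)]
    s = [[None] * (l + 1) for l in range(max_order + 1)]
    c[0][0] = np.ones(n)
    s[0][0] = np.zeros(n)
    for m in range(1, max_order + 1):
        fac = 2 * m - 1
        c[m][m] = fac * (x * c[m - 1][m - 1] - y * s[m - 1][m - 1])
        s[m][m] = fac * (x * s[m - 1][m - 1] + y * c[m - 1][m - 1])
    for m in range(0, max_order):
        if m + 1 <= max_order:
            c[m + 1][m] = (2 * m + 1) * z * c[m][m]
            s[m + 1][m] = (2 * m + 1) * z * s[m][m]
        for l in range(m + 2, max_order + 1):
            c[l][m] = ((2 * l - 1) * z * c[l - 1][m] - (l - 1 + m) * r2 * c[l - 2][m]) / (l - m)
            s[l][m] = ((2 * l - 1) * z * s[l - 1][m] - (l - 1 + m) * r2 * s[l - 2][m]) / (l - m)

    cols = np.empty((n, (max_order + 1) ** 2))
    i = 0
    for l in range(max_order + 1):
        for m in range(-l, l + 1):
            cols[:, i] = s[l][-m] if m < 0 else c[l][m]
            i += 1
    return cols


def evaluate_basis(probes: ProbeArray, max_order: int) -> ProbingMatrix:
    """Build the probing matrix ``P`` for a probe array.

    Parameters
    ----------
    probes
        Probe positions in meters.
    max_order
        Highest solid-harmonic degree to include; the matrix has
        ``(max_order + 1)**2`` columns in the package's ``(l, m)`` ordering.

    Returns
    -------
    ProbingMatrix
        ``P[i, j] = S_{l_j}^{m_j}(r_i)`` with units m^{l_j}, so that
        ``phi = P @ k`` is in radians when ``k`` rows carry rad/m^l.
    """
    if max_order < 0:
        raise ValueError(f"max_order must be >= 0, got {max_order}")
    if probes.n_probes < 1:
        raise ValueError("probe array is empty")
    indexing = HarmonicIndexing(max_order)
    values = _solid_harmonic_table(probes.positions, max_order)
    return ProbingMatrix(values=values, indexing=indexing,
                         positions_hash=_positions_hash(probes.positions))


def order_weights(max_order: int, base: float = 0.1, protect_low: bool = False) -> np.ndarray:
    """Diagonal of the order-weighting matrix Γ, ``Γ_ii = base**l_i``.

    ``base = 0.1`` rescales each degree to comparable magnitude over a 10-cm
    radius volume (equivalently, converts k units from rad/m^l to rad/dm^l).
    With ``protect_low`` the first four entries (degrees 0 and 1) are forced to
    exactly 1, matching the identity block used when low orders are kept
    uncompressed.

    Returns the diagonal as a 1-D array of length ``(max_order + 1)**2``.
    """
    if base <= 0:
        raise ValueError(f"base must be > 0, got {base}")
    orders = HarmonicIndexing(max_order).orders
    gamma = np.asarray(base, dtype=float) ** orders
    if protect_low:
        gamma[: min(4, gamma.size)] = 1.0
    return gamma
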