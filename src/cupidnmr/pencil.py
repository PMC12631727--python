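"""Matrix-pencil initial guesses for damped-sinusoid models.

Subspace (shift-invariance) estimators for sums of exponentially damped
complex sinusoids:

* :func:`mpm_1d` — the classical 1D matrix pencil method on a Hankel matrix,
  used for single-slice diagnostics and as a test oracle.
* :func:`mmempm` — the modified matrix enhancement and matrix pencil method
  for a full 2D grid.  A block-Hankel "enhanced" matrix is formed whose
  (p, q) block is the Hankel matrix of direct-dimension slice p + q; its
  dominant left singular subspace is shift-invariant under advances in either
  time dimension, which exposes the signal poles
  ``z_d = exp((2 pi i f_d - eta_d) tau_d)`` of both dimensions in *paired*
  form.

On noiseless data with M well-separated components the recovery is exact to
numerical precision; under noise the output serves as the initial guess for
the nonlinear refinement stage.

Implementation notes
--------------------
The enhanced matrix is never materialized for large grids: its action on a
vector is a 2D cross-correlation with the data grid, evaluated with FFTs, and
the dominant subspace is obtained with an iterative (ARPACK) partial SVD.
Pole pairing uses simultaneous diagonalization: the eigenvector matrix of a
fixed complex combination ``F1 + mu F2`` of the two shift-invariance maps
diagonalizes both, so the dimension-1 and dimension-2 poles emerge already
paired even when one dimension carries duplicated poles (common in 2DJ data,
where lines of different multiplets share J displacements).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal
from numpy.lib.stride_tricks import as_strided
from scipy.sparse.linalg import LinearOperator, svds

from .core import ExpInfo, FID2D, Oscillator2D, sort_oscillators

__all__ = ["PoleSet", "mpm_1d", "mmempm"]

# deterministic combination coefficient for joint diagonalization; any
# value that breaks degeneracy between the two pole sets works
_MU = 0.61803398875 * np.exp(0.7j)


@dataclass
class PoleSet:
    """Paired signal poles and complex amplitudes of a 2D model.

    ``poles1[m]`` and ``poles2[m]`` belong to the same oscillator;
    ``camplitudes[m] = a_m exp(i phi_m)``.  Growing poles (|z| > 1) are
    clamped to the unit circle (eta = 0) with a warning so the set stays in
    the optimizer's feasible region.
    """

    poles1: np.ndarray
    poles2: np.ndarray
    camplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.poles1 = np.asarray(self.poles1, dtype=np.complex128).ravel()
        self.poles2 = np.asarray(self.poles2, dtype=np.complex128).ravel()
        self.camplitudes = np.asarray(self.camplitudes, dtype=np.complex128).ravel()
        if not (self.poles1.size == self.poles2.size == self.camplitudes.size):
            raise ValueError("poles1, poles2 and camplitudes must have equal length")
        for poles in (self.poles1, self.poles2):
            mag = np.abs(poles)
            grow = mag > 1.0 + 1e-10
            if np.any(grow):
                warnings.warn(
                    f"clamping {int(grow.sum())} growing pole(s) to the unit circle",
                    stacklevel=2,
                )
            np.divide(poles, mag, out=poles, where=mag > 1.0)

    @property
    def M(self) -> int:
        return self.poles1.size

    def to_oscillators(self, expinfo: ExpInfo) -> list[Oscillator2D]:
        """Convert to (a, phi, f1, f2, eta1, eta2) parameters, sorted by (f2, f1)."""
        t1, t2 = expinfo.dwell
        osc = []
        for z1, z2, c in zip(self.poles1, self.poles2, self.camplitudes):
            osc.append(
                Oscillator2D(
                    amplitude=abs(c),
                    phase=float(np.angle(c)),
                    f1=float(np.angle(z1)) / (2 * np.pi * t1),
                    f2=float(np.angle(z2)) / (2 * np.pi * t2),
                    eta1=max(-np.log(max(abs(z1), 1e-300)) / t1, 0.0),
                    eta2=max(-np.log(max(abs(z2), 1e-300)) / t2, 0.0),
                )
            )
        return sort_oscillators(osc)


# ---------------------------------------------------------------------------
# 1D matrix pencil

def mpm_1d(
    fid1d: np.ndarray,
    M: int,
    dwell: float,
    L: int | None = None,
) -> list[Oscillator2D]:
    """1D matrix pencil estimate of M damped sinusoids in a single FID.

    Returns oscillators with the direct-dimension parameters filled in and
    ``f1 = eta1 = 0``.  Requesting more components than the signal holds
    yields near-zero-amplitude spurious oscillators (harmless over-fit).
    """
    y = np.asarray(fid1d, dtype=np.complex128).ravel()
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    if L is None:
        L = max(M, n // 3)
    if not (1 <= M <= min(L, n - L)):
        raise ValueError(f"M={M} infeasible for N={n}, L={L} (need M <= min(L, N-L))")
    H = scipy.linalg.hankel(y[: L + 1], y[L:])  # (L+1) x (N-L)
    if not np.any(np.abs(H) > 0):
        raise ValueError("all-zero input is rank deficient")
    U, _, _ = scipy.linalg.svd(H, full_matrices=False)
    U = U[:, :M]
    F = scipy.linalg.lstsq(U[:-1], U[1:], lapack_driver="gelsd")[0]
    z = scipy.linalg.eigvals(F)
    mag = np.abs(z)
    np.divide(z, mag, out=z, where=mag > 1.0)
    basis = np.power.outer(z, np.arange(n)).T  # N x M Vandermonde
    c = scipy.linalg.lstsq(basis, y, lapack_driver="gelsd")[0]
    ps = PoleSet(np.ones(M, dtype=np.complex128), z, c)
    info = ExpInfo(points=(2, n), dwell=(1.0, float(dwell)))
    osc = ps.to_oscillators(info)
    return [
        Oscillator2D(o.amplitude, o.phase, 0.0, o.f2, 0.0, o.eta2) for o in osc
    ]


# ---------------------------------------------------------------------------
# 2D MMEMPM

class _EnhancedOperator(LinearOperator):
    """Matrix-free action of the enhanced block-Hankel matrix.

    E[(p, i2), (q, j2)] = Y[p + q, i2 + j2]; both E v and E^H u are 2D
    cross-correlations with the data grid, computed via FFT convolution.
    """

    def __init__(self, Y: np.ndarray, L1: int, L2: int):
        n1, n2 = Y.shape
        self.Y = Y
        self.Yc = np.conj(Y)
        self.L1, self.L2 = L1, L2
        self.K1, self.K2 = n1 - L1 + 1, n2 - L2 + 1
        super().__init__(
            dtype=np.complex128, shape=(L1 * L2, self.K1 * self.K2)
        )

    def _matvec(self, v: np.ndarray) -> np.ndarray:
        v2 = v.reshape(self.K1, self.K2)[::-1, ::-1]
        out = scipy.signal.fftconvolve(self.Y, v2, mode="valid")
        return out.ravel()

    def _rmatvec(self, u: np.ndarray) -> np.ndarray:
        u2 = u.reshape(self.L1, self.L2)[::-1, ::-1]
        out = scipy.signal.fftconvolve(self.Yc, u2, mode="valid")
        return out.ravel()


def _enhanced_dense(Y: np.ndarray, L1: int, L2: int) -> np.ndarray:
    n1, n2 = Y.shape
    K1, K2 = n1 - L1 + 1, n2 - L2 + 1
    s0, s1 = Y.strides
    view = as_strided(Y, shape=(L1, L2, K1, K2), strides=(s0, s1, s0, s1))
    return view.reshape(L1 * L2, K1 * K2).copy()


def _signal_subspace(Y: np.ndarray, L1: int, L2: int, M: int) -> np.ndarray:
    """Dominant M left singular vectors of the enhanced matrix."""
    rows, cols = L1 * L2, (Y.shape[0] - L1 + 1) * (Y.shape[1] - L2 + 1)
    small = min(rows, cols)
    if M >= small:
        raise ValueError(f"model order {M} exceeds enhanced-matrix rank bound {small - 1}")
    if small <= 160 or M > small // 2:
        E = _enhanced_dense(Y, L1, L2)
        U, s, _ = scipy.linalg.svd(E, full_matrices=False)
        if s[0] <= 0:
            raise ValueError("all-zero grid is rank deficient")
        return U[:, :M]
    op = _EnhancedOperator(Y, L1, L2)
    # deterministic start vector keeps runs reproducible (ARPACK iterates on
    # the Gram matrix of the smaller side)
    nv = min(rows, cols)
    v0 = np.cos(np.arange(nv) * 0.7) + 1j * np.sin(np.arange(nv) * 0.3)
    U, s, _ = svds(op, k=M, v0=v0, maxiter=5000)
    order = np.argsort(s)[::-1]
    if s[order[0]] <= 0:
        raise ValueError("all-zero grid is rank deficient")
    return U[:, order]


def _paired_poles(U: np.ndarray, L1: int, L2: int, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Paired (z1, z2) via simultaneous diagonalization of the two shift maps."""
    # dimension-1 shift: drop last vs first block-row of the subspace
    F1 = scipy.linalg.lstsq(U[:-L2], U[L2:], lapack_driver="gelsd")[0]
    # dimension-2 shift: within every block, drop last vs first row
    idx = np.flatnonzero(np.arange(L1 * L2) % L2 < L2 - 1)
    F2 = scipy.linalg.lstsq(U[idx], U[idx + 1], lapack_driver="gelsd")[0]
    _, V = scipy.linalg.eig(F1 + _MU * F2)
    Vi = scipy.linalg.inv(V)
    z1 = np.diag(Vi @ F1 @ V).copy()
    z2 = np.diag(Vi @ F2 @ V).copy()
    return z1, z2


def mmempm(
    fid: FID2D,
    M: int,
    L1: int | None = None,
    L2: int | None = None,
) -> list[Oscillator2D]:
    """MMEMPM estimate of M oscillators from a full 2DJ grid.

    Pencil sizes default to floor(N/3) per dimension (minimum 2).  The paired
    poles are converted to oscillator parameters; growing poles are clamped to
    the unit circle and amplitudes/phases follow from a linear least-squares
    fit of the grid against the M Kronecker-product basis signals.
    """
    Y = fid.data
    if not np.any(Y):
        raise ValueError("all-zero grid is rank deficient")
    n1, n2 = fid.expinfo.points
    if n1 < 4 or n2 < 4:
        raise ValueError(f"grid too small for MMEMPM: {fid.expinfo.points}")
    if M < 1:
        raise ValueError("model order must be >= 1")
    if L1 is None:
        L1 = max(2, n1 // 3)
    if L2 is None:
        L2 = max(2, n2 // 3)
    if L1 < 2 or L2 < 2 or L1 > n1 - 1 or L2 > n2 - 1:
        raise ValueError(f"infeasible pencil sizes L1={L1}, L2={L2} for grid {fid.expinfo.points}")
    if M > min((L1 - 1) * L2, L1 * (L2 - 1)):
        raise ValueError(
            f"model order {M} exceeds the shift-invariance rank bound "
            f"{min((L1 - 1) * L2, L1 * (L2 - 1))}"
        )
    U = _signal_subspace(Y, L1, L2, M)
    z1, z2 = _paired_poles(U, L1, L2, M)
    for z in (z1, z2):
        mag = np.abs(z)
        np.divide(z, mag, out=z, where=mag > 1.0)
    # amplitudes: least squares of the full grid against the paired basis
    b1 = np.power.outer(z1, np.arange(n1))  # M x N1
    b2 = np.power.outer(z2, np.arange(n2))  # M x N2
    basis = (b1[:, :, None] * b2[:, None, :]).reshape(M, n1 * n2).T
    c = scipy.linalg.lstsq(basis, Y.ravel(), lapack_driver="gelsd")[0]
    ps = PoleSet(z1, z2, c)
    return ps.to_oscillators(fid.expinfo)
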