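"""Parametric signal model for 2D J-resolved (2DJ) time-domain data.

A 2DJ data set is modelled as a sum of M exponentially damped complex
sinusoids, each described by six parameters: amplitude ``a``, phase ``phi``
(rad), frequencies ``f1``/``f2`` (Hz, indirect/direct dimension) and damping
factors ``eta1``/``eta2`` (s^-1):

    y[n1, n2] = sum_m a_m e^{i phi_m}
                e^{(2 pi i f1_m - eta1_m) n1 tau1}
                e^{(2 pi i f2_m - eta2_m) n2 tau2}  + noise

with zero-based sample indices and dwell times ``tau1``/``tau2``.  Positive
frequencies rotate counterclockwise (e^{+2 pi i f t}); frequencies are offsets
from the carrier, in Hz.

From an estimated parameter set the "-45 degree signal" -- the inverse Fourier
transform of the pure shift spectrum -- is

    y~[n] = sum_m a_m e^{i phi_m} e^{(2 pi i (f2_m - f1_m) - eta2_m) n tau2}

so that each first-order multiplet collapses onto its centre frequency
``f2 - f1`` (the chemical shift), while the direct-dimension linewidth is
retained.

All synthesis used by fitting, residual computation and spectrum construction
flows through this module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Oscillator2D",
    "ExpInfo",
    "FID2D",
    "oscillators_to_array",
    "array_to_oscillators",
    "make_fid2d",
    "make_cupid_signal",
    "subtract_model",
]

_TWO_PI = 2.0 * np.pi


def wrap_phase(phi: float | np.ndarray) -> float | np.ndarray:
    """Wrap phase(s) into (-pi, pi]."""
    wrapped = np.mod(-np.asarray(phi) + np.pi, _TWO_PI)
    out = -(wrapped - np.pi)
    return float(out) if np.isscalar(phi) or np.ndim(phi) == 0 else out


@dataclass(frozen=True)
class Oscillator2D:
    """One damped complex sinusoid of the 2DJ model.

    Parameters are normalized on construction: a negative amplitude is folded
    into the phase (``a -> -a``, ``phi -> phi + pi``), the phase is wrapped
    into ``(-pi, pi]`` and tiny negative dampings (numerical noise from an
    estimator) are clamped to zero.  Genuinely growing signals are rejected.
    """

    amplitude: float
    phase: float
    f1: float
    f2: float
    eta1: float
    eta2: float

    def __post_init__(self) -> None:
        a, phi = float(self.amplitude), float(self.phase)
        if a < 0.0:
            a, phi = -a, phi + np.pi
        phi = wrap_phase(phi)
        eta1, eta2 = float(self.eta1), float(self.eta2)
        tol = 1e-12 * max(1.0, abs(eta1), abs(eta2))
        for name, eta in (("eta1", eta1), ("eta2", eta2)):
            if eta < -tol:
                raise ValueError(f"{name} must be >= 0 (got {eta}): growing signals are not supported")
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "phase", phi)
        object.__setattr__(self, "f1", float(self.f1))
        object.__setattr__(self, "f2", float(self.f2))
        object.__setattr__(self, "eta1", max(eta1, 0.0))
        object.__setattr__(self, "eta2", max(eta2, 0.0))

    @property
    def pure_shift_freq(self) -> float:
        """Centre-frequency contribution ``f2 - f1`` (Hz), the -45 deg position."""
        return self.f2 - self.f1

    @property
    def camplitude(self) -> complex:
        """Complex amplitude ``a e^{i phi}``."""
        return self.amplitude * np.exp(1j * self.phase)


@dataclass(frozen=True)
class ExpInfo:
    """Grid geometry of a 2DJ data set.

    ``points`` are (N1, N2) sample counts, ``dwell`` the dwell times
    (tau1, tau2) in seconds.  ``offset`` holds the transmitter offset per
    dimension in Hz and ``sfo`` the spectrometer frequency in MHz; both are
    used only for axis display (ppm conversion), never in estimation.
    """

    points: tuple[int, int]
    dwell: tuple[float, float]
    offset: tuple[float, float] = (0.0, 0.0)
    sfo: float | None = None

    def __post_init__(self) -> None:
        n1, n2 = self.points
        t1, t2 = self.dwell
        if n1 < 2 or n2 < 2:
            raise ValueError(f"need at least 2 points per dimension, got {self.points}")
        if t1 <= 0 or t2 <= 0:
            raise ValueError(f"dwell times must be positive, got {self.dwell}")
        object.__setattr__(self, "points", (int(n1), int(n2)))
        object.__setattr__(self, "dwell", (float(t1), float(t2)))
        object.__setattr__(self, "offset", (float(self.offset[0]), float(self.offset[1])))

    @property
    def sweep_widths(self) -> tuple[float, float]:
        """Sweep width 1/tau per dimension (Hz)."""
        return (1.0 / self.dwell[0], 1.0 / self.dwell[1])

    def replace(self, **kwargs) -> "ExpInfo":
        return dataclasses.replace(self, **kwargs)

    def timepoints(self, dim: int) -> np.ndarray:
        """Zero-based sample times ``n * tau`` along dimension ``dim`` (0 or 1)."""
        return np.arange(self.points[dim]) * self.dwell[dim]


@dataclass
class FID2D:
    """A complex N1 x N2 time-domain grid bound to its geometry."""

    data: np.ndarray
    expinfo: ExpInfo

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.shape != self.expinfo.points:
            raise ValueError(
                f"data shape {self.data.shape} does not match expinfo.points {self.expinfo.points}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def first_slice(self) -> np.ndarray:
        """The n1 = 0 direct-dimension FID (length N2)."""
        return self.data[0]


# ---------------------------------------------------------------------------
# parameter-array plumbing

_PARAM_COLUMNS = ("amplitude", "phase", "f1", "f2", "eta1", "eta2")


def oscillators_to_array(oscillators: Iterable[Oscillator2D]) -> np.ndarray:
    """Stack oscillators into an (M, 6) float array [a, phi, f1, f2, eta1, eta2]."""
    rows = [(o.amplitude, o.phase, o.f1, o.f2, o.eta1, o.eta2) for o in oscillators]
    if not rows:
        return np.empty((0, 6))
    return np.asarray(rows, dtype=float)


def array_to_oscillators(params: np.ndarray) -> list[Oscillator2D]:
    """Inverse of :func:`oscillators_to_array` (rows normalized on construction)."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if params.size == 0:
        return []
    return [Oscillator2D(*row) for row in params]


def sort_oscillators(oscillators: Sequence[Oscillator2D]) -> list[Oscillator2D]:
    """Deterministic output order: ascending f2, ties broken by ascending f1."""
    return sorted(oscillators, key=lambda o: (o.f2, o.f1))


# ---------------------------------------------------------------------------
# synthesis

def _basis_1d(freqs: np.ndarray, etas: np.ndarray, n: int, dwell: float) -> np.ndarray:
    """(M, n) matrix of e^{(2 pi i f - eta) k tau} for k = 0..n-1."""
    t = np.arange(n) * dwell
    return np.exp(np.outer(_TWO_PI * 1j * np.asarray(freqs) - np.asarray(etas), t))


def make_fid2d(oscillators: Sequence[Oscillator2D], expinfo: ExpInfo) -> FID2D:
    """Synthesize the noiseless model grid for a list of oscillators.

    An empty list yields the all-zero grid.  The model is linear in the
    oscillators, so ``make_fid2d(A + B) == make_fid2d(A) + make_fid2d(B)``.
    """
    n1, n2 = expinfo.points
    p = oscillators_to_array(oscillators)
    if p.shape[0] == 0:
        return FID2D(np.zeros((n1, n2), dtype=np.complex128), expinfo)
    c = p[:, 0] * np.exp(1j * p[:, 1])
    b1 = _basis_1d(p[:, 2], p[:, 4], n1, expinfo.dwell[0])
    b2 = _basis_1d(p[:, 3], p[:, 5], n2, expinfo.dwell[1])
    data = (b1 * c[:, None]).T @ b2
    return FID2D(data, expinfo)


def make_cupid_signal(oscillators: Sequence[Oscillator2D], expinfo: ExpInfo) -> np.ndarray:
    """Synthesize the -45 degree signal (length N2).

    Each oscillator contributes a single exponential at its pure shift
    frequency ``f2 - f1`` with its direct-dimension damping ``eta2``; the
    indirect-dimension damping and the individual frequencies do not appear.
    Estimated phases are retained (see spectra module for the display option).
    """
    n2 = expinfo.points[1]
    p = oscillators_to_array(oscillators)
    if p.shape[0] == 0:
        return np.zeros(n2, dtype=np.complex128)
    c = p[:, 0] * np.exp(1j * p[:, 1])
    basis = _basis_1d(p[:, 3] - p[:, 2], p[:, 5], n2, expinfo.dwell[1])
    return c @ basis


def subtract_model(fid: FID2D, oscillators: Sequence[Oscillator2D]) -> FID2D:
    """Residual grid: data minus the synthesized model.

    With the exact generating parameters of a noiseless grid the result is
    zero to numerical precision; with noisy data it is an estimate of the
    noise grid, used for residual diagnostics.
    """
    model = make_fid2d(oscillators, fid.expinfo)
    return FID2D(fid.data - model.data, fid.expinfo)
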