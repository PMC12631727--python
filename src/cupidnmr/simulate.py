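"""Synthetic first-order 2DJ data sets for testing and validation.

The generator builds grids with the exact statistical structure the signal
model assumes: every first-order line of a weakly coupled multiplet sits at

    f1 = fD            (displacement from the multiplet centre, from couplings)
    f2 = fC + fD       (chemical shift plus displacement)

so the pure shift frequency f2 - f1 = fC is shared across the multiplet.
Couplings to k equivalent partners split each line into k + 1 lines at
displacements (j - k/2) J with binomial weights C(k, j) / 2^k, so the total
amplitude is conserved exactly.

"Strong coupling artifacts" are modelled phenomenologically as unpaired lines
that violate the first-order constraint — sufficient to exercise the
non-first-order purge logic; quantum-mechanical spin dynamics is out of
scope.

Noise is i.i.d. complex Gaussian with standard deviation ``noise_sigma`` per
quadrature.  SNR convention used throughout the package and its tests:

    SNR(dB) = 20 log10( max |noiseless data| / noise_sigma )
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .core import ExpInfo, FID2D, Oscillator2D, make_fid2d

__all__ = [
    "SpinMultipletSpec",
    "ArtifactSpec",
    "Synthetic2DJ",
    "expand_multiplet",
    "generate_2dj",
    "sigma_for_snr",
    "quinine_like_system",
    "quinine_like_expinfo",
    "quinine_like_artifacts",
    "quinine_like_regions",
]


@dataclass(frozen=True)
class SpinMultipletSpec:
    """A first-order multiplet: centre frequency plus a coupling tree.

    ``couplings`` is a list of (J in Hz, number of equivalent partners)
    pairs; an empty list gives a singlet.  ``amplitude`` is the total
    multiplet amplitude (conserved under expansion).
    """

    fc: float
    couplings: tuple[tuple[float, int], ...] = ()
    amplitude: float = 1.0
    eta1: float = 1.0
    eta2: float = 3.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("multiplet amplitude must be > 0")
        cps = tuple((float(j), int(k)) for j, k in self.couplings)
        for j, k in cps:
            if j <= 0:
                raise ValueError(f"coupling constant must be > 0 Hz, got {j}")
            if k < 1:
                raise ValueError(f"partner count must be >= 1, got {k}")
        object.__setattr__(self, "couplings", cps)


@dataclass(frozen=True)
class ArtifactSpec:
    """A line deliberately violating the first-order pairing (f1 != f2 - fC)."""

    f1: float
    f2: float
    amplitude: float
    phase: float = 0.0
    eta1: float = 1.0
    eta2: float = 3.0


@dataclass
class Synthetic2DJ:
    """A generated grid together with its ground truth."""

    fid: FID2D
    oscillators: list[Oscillator2D]
    partition: list[list[int]]  # indices into `oscillators`, one list per multiplet
    artifact_indices: list[int] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int | None = None


def expand_multiplet(spec: SpinMultipletSpec) -> list[Oscillator2D]:
    """Expand a coupling tree into its first-order lines.

    Each coupling (J, k) splits every existing line into k + 1 lines with
    binomial weights; displacements add, weights multiply.  The displacement
    multiset is symmetric about zero and the line amplitudes sum exactly to
    the spec amplitude.
    """
    lines = [(0.0, spec.amplitude)]  # (displacement, amplitude)
    for j, k in spec.couplings:
        new: dict[float, float] = {}
        for disp, amp in lines:
            for split in range(k + 1):
                d = disp + (split - k / 2.0) * j
                w = amp * comb(k, split) / 2.0 ** k
                new[round(d, 12)] = new.get(round(d, 12), 0.0) + w
        lines = sorted(new.items())
    return [
        Oscillator2D(
            amplitude=amp,
            phase=spec.phase,
            f1=disp,
            f2=spec.fc + disp,
            eta1=spec.eta1,
            eta2=spec.eta2,
        )
        for disp, amp in sorted(lines)
    ]


def _check_within_sweep(osc: Oscillator2D, expinfo: ExpInfo, label: str) -> None:
    sw1, sw2 = expinfo.sweep_widths
    if abs(osc.f1) > sw1 / 2:
        raise ValueError(f"{label}: f1 = {osc.f1} Hz aliases (indirect sweep width {sw1} Hz)")
    if abs(osc.f2) > sw2 / 2:
        raise ValueError(f"{label}: f2 = {osc.f2} Hz aliases (direct sweep width {sw2} Hz)")


def generate_2dj(
    specs: list[SpinMultipletSpec],
    artifacts: list[ArtifactSpec],
    expinfo: ExpInfo,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Synthetic2DJ:
    """Synthesize a 2DJ grid with ground truth.

    Returns the noisy grid, the full generating oscillator list (multiplet
    lines first, artifact lines appended), the multiplet partition as index
    lists, and the indices of the artifact lines.  A fixed seed makes the
    output bit-reproducible.
    """
    oscillators: list[Oscillator2D] = []
    partition: list[list[int]] = []
    for i, spec in enumerate(specs):
        lines = expand_multiplet(spec)
        for osc in lines:
            _check_within_sweep(osc, expinfo, f"multiplet {i} (fc={spec.fc} Hz)")
        partition.append(list(range(len(oscillators), len(oscillators) + len(lines))))
        oscillators.extend(lines)
    artifact_indices: list[int] = []
    for i, art in enumerate(artifacts):
        osc = Oscillator2D(art.amplitude, art.phase, art.f1, art.f2, art.eta1, art.eta2)
        _check_within_sweep(osc, expinfo, f"artifact {i}")
        artifact_indices.append(len(oscillators))
        oscillators.append(osc)
    fid = make_fid2d(oscillators, expinfo)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        shape = expinfo.points
        noise = noise_sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        fid = FID2D(fid.data + noise, expinfo)
    return Synthetic2DJ(fid, oscillators, partition, artifact_indices, noise_sigma, seed)


def sigma_for_snr(noiseless: FID2D, snr_db: float) -> float:
    """Per-quadrature noise sigma giving the requested SNR.

    SNR(dB) = 20 log10(max |noiseless data| / sigma).
    """
    peak = float(np.max(np.abs(noiseless.data)))
    if peak == 0:
        raise ValueError("noiseless grid is zero; SNR undefined")
    return peak / 10.0 ** (snr_db / 20.0)


# ---------------------------------------------------------------------------
# canonical fixture: an 8-multiplet proton-like spin system

def quinine_like_expinfo(n1: int = 64, n2: int = 512) -> ExpInfo:
    """Grid geometry typical of a small-molecule 2DJ run, scaled to n1 x n2.

    Indirect sweep width 50 Hz (covers J displacements), direct sweep width
    1 kHz.
    """
    return ExpInfo(points=(n1, n2), dwell=(0.02, 0.001))


def quinine_like_system() -> list[SpinMultipletSpec]:
    """Eight first-order multiplets (2-8 lines each) with distinct couplings.

    Centre frequencies are separated by at least 5 Hz (here far more, as in a
    real small-molecule spectrum), all lines lie within +/- 10 Hz of their
    centres, and amplitudes span a factor ~2.5.
    """
    return [
        SpinMultipletSpec(fc=-180.0, couplings=((7.2, 1),), amplitude=1.0, eta1=0.9, eta2=3.0),
        SpinMultipletSpec(fc=-120.0, couplings=((6.8, 2),), amplitude=1.4, eta1=1.1, eta2=3.5),
        SpinMultipletSpec(fc=-60.0, couplings=((8.0, 1), (2.4, 1)), amplitude=1.2, eta1=0.8, eta2=2.5),
        SpinMultipletSpec(fc=-20.0, couplings=((3.2, 1),), amplitude=0.9, eta1=1.0, eta2=3.4),
        SpinMultipletSpec(fc=30.0, couplings=((7.0, 3),), amplitude=1.5, eta1=1.2, eta2=3.0),
        SpinMultipletSpec(fc=80.0, couplings=((9.6, 1), (3.4, 2)), amplitude=1.2, eta1=0.7, eta2=2.8),
        SpinMultipletSpec(fc=140.0, couplings=((11.0, 1), (4.0, 1)), amplitude=1.2, eta1=1.0, eta2=3.2),
        SpinMultipletSpec(fc=185.0, couplings=((6.4, 1),), amplitude=1.0, eta1=0.9, eta2=3.4),
    ]


def quinine_like_artifacts() -> list[ArtifactSpec]:
    """Three unpaired lines mimicking strong-coupling responses.

    Each sits inside an analysis region with |f1| far above any grouping
    threshold and a pure shift position at least 5 Hz from every genuine
    multiplet centre, so the non-first-order criteria should remove all of
    them and none of the genuine lines.
    """
    return [
        ArtifactSpec(f1=12.0, f2=-115.0, amplitude=0.35, eta1=1.0, eta2=3.0),
        ArtifactSpec(f1=-15.0, f2=70.0, amplitude=0.30, eta1=1.2, eta2=2.5),
        ArtifactSpec(f1=25.0, f2=150.0, amplitude=0.30, eta1=0.8, eta2=3.5),
    ]


def quinine_like_regions() -> tuple[list[tuple[float, float]], list[int]]:
    """Analysis regions centred on each multiplet, with expected line counts.

    The counts (genuine lines plus any artifact falling in the region) are
    the manual model orders a spectroscopist would supply for this crowded,
    low-SNR system, where slice-based order selection under-counts weak
    lines.
    """
    regions = [
        (-205.0, -155.0),
        (-145.0, -95.0),
        (-85.0, -35.0),
        (-45.0, 5.0),
        (5.0, 55.0),
        (55.0, 105.0),
        (115.0, 165.0),
        (160.0, 210.0),
    ]
    orders = [2, 4, 4, 2, 4, 7, 5, 2]
    return regions, orders
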