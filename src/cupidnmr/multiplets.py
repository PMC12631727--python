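"""Multiplet identification and non-first-order purging.

Two estimated signals i, j belong to the same multiplet when their pure shift
frequencies agree within a threshold:

    |(f2_i - f1_i) - (f2_j - f1_j)| < epsilon

Since the pairwise relation is not transitive, it is completed by
single-linkage closure (the minimal consistent completion); a complete-linkage
option exists for cases where chaining over-merges and the threshold cannot
simply be raised.  The default threshold is the digital resolution of the
less well resolved dimension,

    epsilon = max_d 1 / (tau_d N_d),

and can be overridden anywhere it is used (crowded spectra often need a
larger value).

A signal is purged as non-first-order only when BOTH criteria hold:

1. it is not grouped with any other signal, and
2. its indirect-dimension frequency is far from zero: |f1| > epsilon

— the signature of a strong-coupling artifact or a fitted noise component.
A genuine singlet is a singleton with f1 ~ 0 and is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .core import ExpInfo, Oscillator2D

__all__ = [
    "Multiplet",
    "PurgeReport",
    "default_threshold",
    "group_multiplets",
    "purge_non_first_order",
]


@dataclass(frozen=True)
class Multiplet:
    """A group of oscillators sharing a centre frequency.

    ``center`` is the amplitude-weighted mean of the members' pure shift
    frequencies f2 - f1; ``total_amplitude`` is the sum of member amplitudes
    (proportional to the multiplet integral).
    """

    members: tuple[int, ...]
    center: float
    total_amplitude: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PurgeReport:
    """Which oscillators were removed and which criteria fired for each."""

    purged: list[int] = field(default_factory=list)
    criteria: dict[int, list[str]] = field(default_factory=dict)
    epsilon: float = 0.0


def default_threshold(expinfo: ExpInfo) -> float:
    """Grouping threshold: digital resolution of the worse-resolved dimension (Hz)."""
    (n1, n2), (t1, t2) = expinfo.points, expinfo.dwell
    return max(1.0 / (t1 * n1), 1.0 / (t2 * n2))


def _cluster_labels(values: np.ndarray, eps: float, linkage: str) -> np.ndarray:
    n = values.size
    if n == 1:
        return np.zeros(1, dtype=int)
    if linkage == "single":
        # exact 1D single linkage: chain while consecutive gaps are < eps
        order = np.argsort(values, kind="stable")
        labels = np.empty(n, dtype=int)
        lab = 0
        labels[order[0]] = 0
        for prev, cur in zip(order[:-1], order[1:]):
            if values[cur] - values[prev] >= eps:
                lab += 1
            labels[cur] = lab
        return labels
    if linkage == "complete":
        d = scipy.spatial.distance.pdist(values[:, None])
        Z = scipy.cluster.hierarchy.complete(d)
        fl = scipy.cluster.hierarchy.fcluster(Z, t=eps * (1 - 1e-12), criterion="distance")
        return fl - 1
    raise ValueError(f"unknown linkage {linkage!r}")


def group_multiplets(
    oscillators: list[Oscillator2D],
    epsilon: float,
    linkage: str = "single",
) -> list[Multiplet]:
    """Partition oscillators into multiplets by pure shift frequency.

    Every oscillator lands in exactly one multiplet (singletons allowed);
    multiplets are returned sorted by centre frequency.  The number of
    multiplets is non-increasing in ``epsilon`` for single linkage.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not oscillators:
        return []
    v = np.array([o.pure_shift_freq for o in oscillators])
    a = np.array([o.amplitude for o in oscillators])
    labels = _cluster_labels(v, float(epsilon), linkage)
    out = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        w = a[idx]
        center = float(np.average(v[idx], weights=w)) if w.sum() > 0 else float(v[idx].mean())
        out.append(Multiplet(tuple(int(i) for i in idx), center, float(w.sum())))
    return sorted(out, key=lambda m: m.center)


def purge_non_first_order(
    oscillators: list[Oscillator2D],
    multiplets: list[Multiplet],
    epsilon: float,
) -> tuple[list[Oscillator2D], PurgeReport]:
    """Remove signals that are ungrouped AND have |f1| > epsilon.

    Returns the kept oscillators (original order) and a report listing every
    purge decision.  Idempotent: purging an already-purged set is a no-op.
    """
    report = PurgeReport(epsilon=float(epsilon))
    singleton = set()
    for m in multiplets:
        if len(m) == 1:
            singleton.add(m.members[0])
    kept = []
    for i, osc in enumerate(oscillators):
        fired = []
        if i in singleton:
            fired.append("ungrouped")
        if abs(osc.f1) > epsilon:
            fired.append("|f1| > epsilon")
        if len(fired) == 2:
            report.purged.append(i)
            report.criteria[i] = fired
        else:
            kept.append(osc)
    return kept, report
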