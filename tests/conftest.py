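import numpy as np
import pytest

from cupidnmr import ExpInfo, Oscillator2D, make_fid2d


@pytest.fixture
def small_expinfo() -> ExpInfo:
    """32 x 128 grid, 50 Hz / 1 kHz sweep widths."""
    return ExpInfo(points=(32, 128), dwell=(0.02, 0.001))


@pytest.fixture
def three_oscillators() -> list[Oscillator2D]:
    return [
        Oscillator2D(1.0, 0.1, -3.5, 196.5, 1.0, 3.0),
        Oscillator2D(0.7, 0.1, 3.5, 203.5, 1.5, 2.0),
        Oscillator2D(1.2, 0.1, 0.0, 300.0, 0.8, 2.5),
    ]


def random_separated_oscillators(rng: np.random.Generator, expinfo: ExpInfo, m_max: int = 5):
    """Random parameter draw with pairwise separations > 2/(N tau) per dimension."""
    (n1, n2), (t1, t2) = expinfo.points, expinfo.dwell
    m = int(rng.integers(1, m_max + 1))
    sw1, sw2 = 1 / t1, 1 / t2

    def draw(n_pts, dwell, lo, hi):
        sep = 2.0 / (n_pts * dwell)
        while True:
            f = np.sort(rng.uniform(lo, hi, m))
            if m == 1 or np.min(np.diff(f)) > sep:
                return f

    f1 = draw(n1, t1, -0.4 * sw1, 0.4 * sw1)
    f2 = draw(n2, t2, -0.4 * sw2, 0.4 * sw2)
    a = rng.uniform(0.5, 2.0, m)
    phi = rng.uniform(-np.pi, np.pi, m)
    e1 = rng.uniform(0.0, 2.0, m)
    e2 = rng.uniform(0.5, 4.0, m)
    osc = [Oscillator2D(*p) for p in zip(a, phi, f1, f2, e1, e2)]
    return sorted(osc, key=lambda o: (o.f2, o.f1))


def params_array(oscillators):
    return np.array(
        [[o.amplitude, o.phase, o.f1, o.f2, o.eta1, o.eta2] for o in oscillators]
    )


def max_relative_error(est, truth):
    """Worst relative parameter error between matched (f2, f1)-sorted lists."""
    E, T = params_array(est), params_array(truth)
    return float(np.max(np.abs(E - T) / np.maximum(np.abs(T), 1.0)))
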