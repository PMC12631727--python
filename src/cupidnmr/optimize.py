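"""Nonlinear refinement of oscillator parameters.

The initial (matrix-pencil) guess is refined by minimizing

    F(theta) = sum_{n1,n2} |y[n1,n2] - model_theta[n1,n2]|^2
               + lambda * VarCirc(phi_1, ..., phi_M)

over all 6M real parameters, where VarCirc is the *circular* variance
``1 - |mean_m exp(i phi_m)|`` — phases live on the circle, and the circular
form is wrap-safe.  The regularizer breaks the near-degeneracy between a
common phase roll and amplitude changes without biasing amplitudes; by
default lambda is scale-matched to the problem (1e-3 times the initial
residual sum-of-squares per unit variance), and lambda = 0 reduces the cost
exactly to the RSS.

Minimization is damped (trust-region style) Gauss-Newton with analytic
first derivatives: only steps that lower the cost are accepted, so descent
is monotone.  The model is separable — every partial derivative of one
oscillator's signal is a Kronecker product of a dimension-1 and a
dimension-2 vector — so the full Gauss-Newton normal matrix assembles from
six M x M Gram matrices per dimension in O(M^2 (N1 + N2)) time; neither the
Jacobian nor a Hessian is ever materialized over the data grid.

Amplitude positivity is enforced by sign-flip normalization after
optimization rather than bound constraints (keeps the problem smooth);
dampings are softly penalized below zero and clamped on output.  When
fitting a frequency-filtered sub-FID, direct-dimension frequencies can be
softly confined to the filter pass-band so oscillators cannot wander into
the suppressed region.

Oscillators whose refined amplitude falls below a threshold fraction of the
largest amplitude are purged (they model noise, not signal), logged, and
the remainder re-optimized.

Parameter uncertainties come from the observed-information approximation:
the diagonal of the inverse Gauss-Newton curvature of the *unregularized*
RSS, scaled by the residual variance estimate RSS / (2 N1 N2 - 6M).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core import (
    FID2D,
    Oscillator2D,
    array_to_oscillators,
    oscillators_to_array,
    sort_oscillators,
)

__all__ = ["FitConfig", "FitReport", "fit", "parameter_errors"]

_TWO_PI = 2.0 * np.pi

# (dim1 time power, dim2 time power) of each parameter's derivative vector
_DERIV_POWERS = ((0, 0), (0, 0), (1, 0), (0, 1), (1, 0), (0, 1))


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the refinement stage.

    ``phase_reg_weight``: absolute regularizer weight lambda; ``None`` selects
    the scale-matched default 1e-3 * RSS(initial guess).
    ``purge_threshold``: oscillators with amplitude below this fraction of the
    largest amplitude are removed after convergence.
    ``f2_bounds``: optional (centre, halfwidth) in Hz; direct-dimension
    frequencies are quadratically penalized outside centre +/- halfwidth.
    """

    phase_reg_weight: float | None = None
    max_iter: int = 200
    grad_tol: float = 1e-10
    purge_threshold: float = 1e-3
    f2_bounds: tuple[float, float] | None = None
    compute_errors: bool = True

    def __post_init__(self) -> None:
        if self.phase_reg_weight is not None and self.phase_reg_weight < 0:
            raise ValueError("phase_reg_weight must be >= 0")
        if not 0.0 <= self.purge_threshold < 1.0:
            raise ValueError("purge_threshold must be in [0, 1)")


@dataclass
class FitReport:
    """Diagnostics of one refinement run."""

    initial_cost: float
    final_cost: float
    iterations: int
    converged: bool
    param_errors: np.ndarray | None = None  # (M, 6), columns as the parameter array
    purged: list[dict] = field(default_factory=list)
    lam: float = 0.0


class _ModelWorkspace:
    """Basis evaluation and derivative algebra for one data grid."""

    def __init__(self, y: np.ndarray, tau1: float, tau2: float):
        self.y = y
        self.n1, self.n2 = y.shape
        self.t1 = np.arange(self.n1) * tau1
        self.t2 = np.arange(self.n2) * tau2

    def bases(self, p: np.ndarray):
        a, phi, f1, f2, e1, e2 = p.T
        c = a * np.exp(1j * phi)
        U = np.exp(np.outer(_TWO_PI * 1j * f1 - e1, self.t1))  # M x N1
        V = np.exp(np.outer(_TWO_PI * 1j * f2 - e2, self.t2))  # M x N2
        return c, U, V

    def model(self, c, U, V) -> np.ndarray:
        return (U * c[:, None]).T @ V

    @staticmethod
    def _prefactors(p: np.ndarray, c: np.ndarray):
        eiphi = np.exp(1j * p[:, 1])
        return (
            eiphi,  # d/da
            1j * c,  # d/dphi
            _TWO_PI * 1j * c,  # d/df1
            _TWO_PI * 1j * c,  # d/df2
            -c,  # d/deta1
            -c,  # d/deta2
        )

    def gradient_rss(self, p: np.ndarray, c, U, V, r: np.ndarray) -> np.ndarray:
        """Gradient of sum |r|^2 wrt the 6M parameters, r = model - y."""
        R = np.conj(r)
        A = U @ R  # M x N2
        S = np.einsum("mn,mn->m", A, V)
        S1 = np.einsum("mn,mn->m", (U * self.t1[None, :]) @ R, V)
        S2 = np.einsum("mn,mn->m", A, V * self.t2[None, :])
        q = self._prefactors(p, c)
        sums = (S, S, S1, S2, S1, S2)
        g = np.empty_like(p)
        for k in range(6):
            g[:, k] = 2.0 * (q[k] * sums[k]).real
        return g.ravel()

    def gauss_newton_matrix(self, p: np.ndarray, c, U, V) -> np.ndarray:
        """2 Re(J^H J) assembled from separable per-dimension Gram matrices."""
        m = p.shape[0]
        U1 = U * self.t1[None, :]
        V1 = V * self.t2[None, :]
        Uc, U1c = np.conj(U), np.conj(U1)
        Vc, V1c = np.conj(V), np.conj(V1)
        g1 = {
            (0, 0): Uc @ U.T,
            (0, 1): Uc @ U1.T,
            (1, 0): U1c @ U.T,
            (1, 1): U1c @ U1.T,
        }
        g2 = {
            (0, 0): Vc @ V.T,
            (0, 1): Vc @ V1.T,
            (1, 0): V1c @ V.T,
            (1, 1): V1c @ V1.T,
        }
        q = self._prefactors(p, c)
        H = np.empty((6 * m, 6 * m))
        idx = [np.arange(m) * 6 + k for k in range(6)]
        for k in range(6):
            ak, bk = _DERIV_POWERS[k]
            for l in range(6):
                al, bl = _DERIV_POWERS[l]
                block = (
                    np.conj(q[k])[:, None]
                    * q[l][None, :]
                    * g1[(ak, al)]
                    * g2[(bk, bl)]
                )
                H[np.ix_(idx[k], idx[l])] = 2.0 * block.real
        return H


def _phase_reg(phi: np.ndarray, lam: float):
    """lam * (1 - |mean exp(i phi)|) and its gradient."""
    m = phi.size
    zbar = np.exp(1j * phi).mean()
    r = abs(zbar)
    val = lam * (1.0 - r)
    grad = np.zeros(m)
    if r > 1e-14:
        grad = -lam * (zbar.imag * np.cos(phi) - zbar.real * np.sin(phi)) / (m * r)
    return val, grad


def _penalties(p: np.ndarray, bounds, w: float):
    """Soft negative-damping and out-of-band-f2 penalties: value, gradient, diag Hessian."""
    val = 0.0
    g = np.zeros_like(p)
    h = np.zeros_like(p)
    for j in (4, 5):
        neg = np.minimum(p[:, j], 0.0)
        val += w * float(neg @ neg)
        g[:, j] = 2.0 * w * neg
        h[:, j] = np.where(p[:, j] < 0, 2.0 * w, 0.0)
    if bounds is not None:
        centre, hw = bounds
        dev = p[:, 3] - centre
        out = np.maximum(np.abs(dev) - hw, 0.0)
        wb = w / max(hw, 1e-12) ** 2
        val += wb * float(out @ out)
        g[:, 3] += 2.0 * wb * out * np.sign(dev)
        h[:, 3] += np.where(out > 0, 2.0 * wb, 0.0)
    return val, g.ravel(), h.ravel()


def _cost_state(theta, ws, lam, bounds, bound_w):
    p = theta.reshape(-1, 6)
    c, U, V = ws.bases(p)
    r = ws.model(c, U, V) - ws.y
    cost = float(np.vdot(r, r).real)
    reg, reg_g = _phase_reg(p[:, 1], lam)
    pen, pen_g, pen_h = _penalties(p, bounds, bound_w)
    cost += reg + pen
    return cost, (p, c, U, V, r, reg_g, pen_g, pen_h)


def _normalize_params(p: np.ndarray) -> np.ndarray:
    """Fold negative amplitudes into phases, wrap phases, clamp dampings."""
    p = p.copy()
    neg = p[:, 0] < 0
    p[neg, 0] = -p[neg, 0]
    p[neg, 1] += np.pi
    p[:, 1] = -(np.mod(-p[:, 1] + np.pi, _TWO_PI) - np.pi)
    p[:, 4:] = np.maximum(p[:, 4:], 0.0)
    return p


def _minimize_gn(theta0, ws, lam, bounds, bound_w, max_iter, grad_tol):
    """Damped Gauss-Newton with monotone (accept-only-improving) steps."""
    theta = theta0.copy()
    cost, state = _cost_state(theta, ws, lam, bounds, bound_w)
    mu = 1e-4  # LM damping relative to the curvature diagonal
    n_iter = 0
    converged = False
    gtol_abs = None
    while n_iter < max_iter:
        p, c, U, V, r, reg_g, pen_g, pen_h = state
        g = ws.gradient_rss(p, c, U, V, r)
        g.reshape(-1, 6)[:, 1] += reg_g
        g += pen_g
        gmax = float(np.max(np.abs(g)))
        if gtol_abs is None:
            gtol_abs = max(grad_tol * max(gmax, 1.0), 1e3 * np.finfo(float).tiny)
        if gmax <= gtol_abs:
            converged = True
            break
        H = ws.gauss_newton_matrix(p, c, U, V)
        H[np.diag_indices_from(H)] += pen_h
        d = np.maximum(np.diag(H), 1e-300)
        accepted = False
        for _try in range(12):
            A = H + np.diag(mu * d)
            try:
                with warnings.catch_warnings():
                    # near-singular curvature is expected while damping adapts
                    warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                    step = scipy.linalg.solve(A, -g, assume_a="pos")
                if not np.all(np.isfinite(step)):
                    raise scipy.linalg.LinAlgError("non-finite step")
            except scipy.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + step
            cand_cost, cand_state = _cost_state(cand, ws, lam, bounds, bound_w)
            if np.isfinite(cand_cost) and cand_cost <= cost:
                rel_drop = (cost - cand_cost) / max(cost, 1e-300)
                theta, cost, state = cand, cand_cost, cand_state
                mu = max(mu / 3.0, 1e-12)
                accepted = True
                n_iter += 1
                if rel_drop < 1e-14:
                    converged = True
                break
            mu *= 4.0
        if not accepted:
            converged = True  # no improving step exists at any damping: at a minimum
            break
        if converged:
            break
    return theta, cost, n_iter, converged


def fit(
    fid: FID2D,
    init: list[Oscillator2D],
    cfg: FitConfig = FitConfig(),
) -> tuple[list[Oscillator2D], FitReport]:
    """Refine an initial oscillator list against a 2DJ grid.

    Returns the refined, normalized, (f2, f1)-sorted oscillators and a
    :class:`FitReport`.  Low-amplitude oscillators are purged and logged;
    after a purge the remaining set is re-optimized.
    """
    if not init:
        raise ValueError("initial oscillator list must be nonempty")
    if not np.all(np.isfinite(fid.data)):
        raise ValueError("data grid contains non-finite values")
    tau1, tau2 = fid.expinfo.dwell
    scale = float(np.max(np.abs(fid.data)))
    scale = scale if scale > 0 else 1.0
    ws = _ModelWorkspace(fid.data / scale, tau1, tau2)
    p0 = oscillators_to_array(init)
    p0[:, 0] /= scale

    c0, U0, V0 = ws.bases(p0)
    r0 = ws.model(c0, U0, V0) - ws.y
    rss0 = float(np.vdot(r0, r0).real)
    lam = 1e-3 * rss0 if cfg.phase_reg_weight is None else float(cfg.phase_reg_weight)
    bound_w = max(rss0, 1e-12)

    purged: list[dict] = []
    theta = p0.ravel().copy()
    initial_cost = _cost_state(theta, ws, lam, cfg.f2_bounds, bound_w)[0]
    total_iter = 0
    converged = False
    final_cost = initial_cost
    for _round in range(4):
        theta, cost, n_iter, converged = _minimize_gn(
            theta, ws, lam, cfg.f2_bounds, bound_w, cfg.max_iter, cfg.grad_tol
        )
        total_iter += n_iter
        final_cost = min(cost, final_cost)
        p = _normalize_params(theta.reshape(-1, 6))
        amax = p[:, 0].max() if p.size else 0.0
        low = p[:, 0] < cfg.purge_threshold * amax
        if not np.any(low) or np.all(low):
            theta = p.ravel()
            break
        for row in p[low]:
            row = row.copy()
            row[0] *= scale
            purged.append(
                {"params": row.tolist(), "reason": "amplitude below purge threshold"}
            )
        p = p[~low]
        theta = p.ravel()

    p = theta.reshape(-1, 6).copy()
    p[:, 0] *= scale
    oscillators = sort_oscillators(array_to_oscillators(p))
    report = FitReport(
        initial_cost=initial_cost * scale**2,
        final_cost=final_cost * scale**2,
        iterations=total_iter,
        converged=converged,
        purged=purged,
        lam=lam * scale**2,
    )
    if cfg.compute_errors and oscillators:
        report.param_errors = parameter_errors(fid, oscillators)
    return oscillators, report


def parameter_errors(fid: FID2D, oscillators: list[Oscillator2D]) -> np.ndarray:
    """Standard errors of the 6M parameters at a cost minimum, shape (M, 6).

    Observed-information approximation: covariance = sigma^2 (Re J^H J)^{-1}
    with sigma^2 = RSS / (2 N1 N2 - 6M) estimated from the residual (per
    quadrature).  Near-singular curvature yields NaN entries with a warning.
    """
    if not oscillators:
        return np.empty((0, 6))
    p = oscillators_to_array(oscillators)
    tau1, tau2 = fid.expinfo.dwell
    ws = _ModelWorkspace(fid.data, tau1, tau2)
    c, U, V = ws.bases(p)
    r = ws.model(c, U, V) - fid.data
    n_obs = 2 * fid.data.size
    dof = n_obs - 6 * p.shape[0]
    if dof <= 0:
        warnings.warn("no residual degrees of freedom; errors unavailable", stacklevel=2)
        return np.full((p.shape[0], 6), np.nan)
    sigma2 = float(np.vdot(r, r).real) / dof
    G = ws.gauss_newton_matrix(p, c, U, V) / 2.0  # Re(J^H J)
    # scale-equilibrate before inversion for a meaningful condition estimate
    d = np.sqrt(np.maximum(np.diag(G), 1e-300))
    Gs = G / np.outer(d, d)
    try:
        diag = np.diag(scipy.linalg.inv(Gs)) / d**2
        bad = ~np.isfinite(diag) | (diag < 0)
    except scipy.linalg.LinAlgError:
        warnings.warn("singular curvature; using pseudo-inverse for errors", stacklevel=2)
        diag = np.diag(scipy.linalg.pinv(Gs)) / d**2
        bad = ~np.isfinite(diag) | (diag <= 0)
    if np.any(bad):
        warnings.warn(
            f"errors unavailable for {int(bad.sum())} parameter(s) (singular curvature)",
            stacklevel=2,
        )
        diag = np.where(bad, np.nan, diag)
    return np.sqrt(sigma2 * diag).reshape(-1, 6)
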