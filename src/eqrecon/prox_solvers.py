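"""Classical proximal operators, total variation, and the proximal gradient method.

The proximal operator of a functional J is

    prox_J(u) = argmin_v  ||u - v||^2 / 2 + J(v).

If J is invariant under a unitary group action (J(rho(g) u) = J(u)) then
prox_J commutes with that action.  Two concrete cases are provided: the
Tikhonov functional (lam/2)||u||^2, whose prox u / (1 + tau*lam) is exactly
rotation equivariant, and the isotropic total variation seminorm, whose prox
is computed by a convergent dual projection iteration.

The default TV discretisation uses forward differences with Neumann
boundary, which is the field standard but not exactly invariant under 90
degree rotations.  A symmetrised variant (the average of the forward-difference
TV over the four rotated stencils) is exactly Z4 invariant at the discrete
level, which makes the prox-equivariance property testable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import solveh_banded

from .forward_models import LinearOperatorPair, operator_norm
from .groups import CyclicGroup, rotate_array

# ---------------------------------------------------------------------------
# Functionals
# ---------------------------------------------------------------------------


@dataclass
class Functional:
    """A regulariser: its value and its proximal map prox_{tau J}."""

    evaluate: Callable[[np.ndarray], float]
    prox: Callable[[np.ndarray, float], np.ndarray]
    convexity_note: str = ""


def prox_tikhonov(u: np.ndarray, tau: float, lam: float) -> np.ndarray:
    """prox of (lam/2)||.||^2: simple shrinkage u / (1 + tau*lam)."""
    if tau < 0 or lam < 0:
        raise ValueError("tau and lam must be nonnegative")
    return u / (1.0 + tau * lam)


def tikhonov_functional(lam: float) -> Functional:
    return Functional(
        evaluate=lambda u: 0.5 * lam * float(np.sum(u * u)),
        prox=lambda u, tau: prox_tikhonov(u, tau, lam),
        convexity_note="strongly convex",
    )


def zero_functional() -> Functional:
    return Functional(
        evaluate=lambda u: 0.0,
        prox=lambda u, tau: u,
        convexity_note="identically zero",
    )


# ---------------------------------------------------------------------------
# Total variation
# ---------------------------------------------------------------------------


def _grad_fwd(u: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundary: output [2, H, W]."""
    g = np.zeros((2,) + u.shape)
    g[0, :-1, :] = u[1:, :] - u[:-1, :]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    return g


def _div_fwd(p: np.ndarray) -> np.ndarray:
    """Adjoint of _grad_fwd (the negative divergence with matching boundary)."""
    div = np.zeros(p.shape[1:])
    div[:-1, :] += p[0, :-1, :]
    div[1:, :] -= p[0, :-1, :]
    div[:, :-1] += p[1, :, :-1]
    div[:, 1:] -= p[1, :, :-1]
    return -div


def _grad_sym(u: np.ndarray) -> np.ndarray:
    """Stacked forward-difference gradients over the 4 rotated stencils, each
    weighted 1/4: output [4, 2, N, N] (block r lives on the r-times rotated
    grid).  Requires a square image, since the stencil rotations must map the
    grid onto itself."""
    if u.shape[0] != u.shape[1]:
        raise ValueError("symmetrised TV requires a square image")
    return np.stack([0.25 * _grad_fwd(np.rot90(u, r)) for r in range(4)])


def _grad_sym_adjoint(p: np.ndarray) -> np.ndarray:
    out = np.zeros(p.shape[2:])
    for r in range(4):
        out += np.rot90(_div_fwd(0.25 * p[r]), -r)
    return out


def tv_seminorm(u: np.ndarray, symmetrised: bool = False) -> float:
    """Discrete isotropic TV: sum of Euclidean norms of the pixelwise gradient.

    The symmetrised variant averages the forward-difference TV over the four
    90-degree rotations of the stencil and is exactly Z4 invariant.
    """
    u = np.asarray(u, dtype=float)
    if symmetrised:
        g = _grad_sym(u)
        return float(np.sqrt(np.sum(g * g, axis=1)).sum())
    g = _grad_fwd(u)
    return float(np.sqrt(np.sum(g * g, axis=0)).sum())


def prox_tv(
    u: np.ndarray,
    tau: float,
    tol: float = 1e-8,
    max_iter: int = 2000,
    symmetrised: bool = False,
    return_info: bool = False,
):
    """prox of tau*TV by projected gradient ascent on the dual problem.

    The dual variable is a per-pixel vector field constrained to the unit
    ball; the fixed step is 1/8 (a convergent regime for the difference
    operator, whose squared norm is at most 8).  Iterations stop when the
    relative duality gap ``gap / (||u||^2/2)`` falls below ``tol`` or at
    ``max_iter`` (in which case the result carries ``converged=False``).
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    u = np.asarray(u, dtype=float)
    info = {"converged": True, "n_iter": 0, "gap": 0.0}
    if tau == 0 or not np.any(u):
        out = u.copy()
        return (out, info) if return_info else out

    if symmetrised:
        D, Dt, axis = _grad_sym, _grad_sym_adjoint, 1
    else:
        D, Dt, axis = _grad_fwd, _div_fwd, 0

    p = np.zeros_like(D(u))
    unorm2 = float(np.sum(u * u))
    step = 1.0 / 8.0
    v = u
    for it in range(1, max_iter + 1):
        dtp = Dt(p)
        v = u - tau * dtp
        grad = D(v)
        p = p + (step / tau) * grad
        mag = np.sqrt(np.sum(p * p, axis=axis, keepdims=True))
        p = p / np.maximum(1.0, mag)
        if it % 10 == 0 or it == max_iter:
            dtp = Dt(p)
            v = u - tau * dtp
            g = D(v)
            primal = 0.5 * float(np.sum((v - u) ** 2)) + tau * float(
                np.sqrt(np.sum(g * g, axis=axis)).sum()
            )
            dual = tau * float(np.sum(dtp * u)) - 0.5 * tau**2 * float(
                np.sum(dtp * dtp)
            )
            gap = max(primal - dual, 0.0)
            info.update(n_iter=it, gap=gap)
            if gap <= tol * 0.5 * unorm2:
                break
    else:  # pragma: no cover - defensive
        pass
    if info["gap"] > tol * 0.5 * unorm2:
        info["converged"] = False
    out = u - tau * Dt(p)
    return (out, info) if return_info else out


def tv_functional(weight: float = 1.0, symmetrised: bool = False, tol: float = 1e-8) -> Functional:
    return Functional(
        evaluate=lambda u: weight * tv_seminorm(u, symmetrised=symmetrised),
        prox=lambda u, tau: prox_tv(u, tau * weight, tol=tol, symmetrised=symmetrised),
        convexity_note="convex, 1-homogeneous",
    )


def anisotropic_demo_prox(u: np.ndarray, tau: float, lam: float = 1.0) -> np.ndarray:
    """prox of (lam/2)*||horizontal differences||^2: smooths along rows only.

    Deliberately NOT rotation equivariant; used as a negative control in the
    prox-equivariance harness.
    """
    w = u.shape[1]
    # (I + tau*lam * D^T D) with D the 1-D forward difference along each row
    ab = np.zeros((2, w))
    ab[1, :] = 1.0 + 2.0 * tau * lam
    ab[1, 0] = ab[1, -1] = 1.0 + tau * lam
    ab[0, 1:] = -tau * lam
    return solveh_banded(ab, u.T).T


# ---------------------------------------------------------------------------
# Proximal gradient method
# ---------------------------------------------------------------------------


def proximal_gradient(
    y: np.ndarray,
    op: LinearOperatorPair,
    functional: Functional,
    n_iter: int,
    tau: float | np.ndarray | None = None,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate u <- prox_{tau J}(u - tau * grad E_y(u)) from u0 (default 0).

    ``tau`` may be a scalar or a per-iteration array; the default is
    1 / ||A||^2 with the operator norm estimated by power iteration.  Returns
    the final iterate and the objective trace E_y + J (evaluated after each
    step).  Raises on a divergent objective.
    """
    u = np.zeros(op.in_shape) if u0 is None else np.array(u0, dtype=float)
    if tau is None:
        tau = 1.0 / operator_norm(op) ** 2
    taus = np.broadcast_to(np.asarray(tau, dtype=float), (n_iter,))

    def objective(v: np.ndarray) -> float:
        r = op.apply(v) - y
        return 0.5 * float(np.sum(r * r)) + functional.evaluate(v)

    trace = np.empty(n_iter + 1)
    trace[0] = objective(u)
    for i in range(n_iter):
        t = float(taus[i])
        grad = op.adjoint(op.apply(u) - y)
        u = functional.prox(u - t * grad, t)
        trace[i + 1] = objective(u)
        if not np.isfinite(trace[i + 1]) or trace[i + 1] > 1e6 * (abs(trace[0]) + 1.0):
            raise FloatingPointError(
                f"proximal gradient diverged at iteration {i + 1}: "
                f"objective {trace[i + 1]:.3e}"
            )
    return u, trace


# ---------------------------------------------------------------------------
# Prox-equivariance harness
# ---------------------------------------------------------------------------


def check_prox_equivariance(
    prox: Callable[[np.ndarray], np.ndarray],
    group: CyclicGroup,
    trials: int = 3,
    shape: tuple[int, int] = (16, 16),
    seed: int = 0,
) -> float:
    """Max relative defect ||prox(g.u) - g.prox(u)|| / ||prox(g.u)|| over random
    scalar images and all group elements (scalar-field rotation action)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(trials):
        u = rng.normal(size=shape)
        pu = prox(u)
        for k in group.elements:
            if k == 0:
                continue
            lhs = prox(rotate_array(u, group, k))
            rhs = rotate_array(pu, group, k)
            denom = np.linalg.norm(lhs) + np.finfo(float).eps
            worst = max(worst, float(np.linalg.norm(lhs - rhs) / denom))
    return worst
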