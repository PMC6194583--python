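"""Smoke-veil estimation by isotropic total-variation minimization.

The additive smoke veil ``F`` contributed by light scattered off surgical
smoke is assumed to be (i) spatially smooth and (ii) nearly equal across
the R, G, B channels.  Both assumptions are encoded in a single energy

    E(F) = (gamma / 2) * ||F - I||^2
         + sum_i sqrt( theta_x^2 [Dx F]_i^2
                     + theta_y^2 [Dy F]_i^2
                     + theta_c^2 [Dc F]_i^2 ),

where ``I`` is the degraded image, ``Dx, Dy`` are forward differences in
the two spatial directions and ``Dc`` is the forward difference across the
channel axis — an isotropic 3-D TV norm whose channel direction penalizes
inter-channel differences the way the temporal direction of a video-TV
model penalizes flicker.

The energy is minimized with ADMM: the problem is split as
``min (gamma/2)||F - I||^2 + ||u||_2  s.t.  D F = u`` with scaled
difference operator ``D = [theta_x Dx; theta_y Dy; theta_c Dc]``, giving
three updates per iteration:

* **F-update** — a quadratic solve ``(gamma + rho D^T D) F = gamma I +
  rho D^T u - D^T r``, diagonalized exactly by the 3-D FFT because all
  difference operators use circular (periodic) boundaries;
* **u-update** — the isotropic vector soft-threshold (shrinkage) coupling
  the three directions;
* **r-update** — the standard multiplier ascent step.

All boundaries are circular, including the channel axis of length 3
(B wraps to R); this is what makes the FFT solve exact rather than
approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .image_io import validate_image

__all__ = [
    "SolverParams",
    "ADMMState",
    "SolverDiagnostics",
    "SingularSolveError",
    "SolverDivergenceError",
    "forward_diff",
    "adjoint_diff",
    "isotropic_tv",
    "energy",
    "solve_F_subproblem",
    "shrink_u",
    "update_multipliers",
    "estimate_smoke_veil",
]

#: axis index in an (H, W, 3) array for each difference direction
_AXIS = {"x": 1, "y": 0, "c": 2}

_DIRECTIONS = ("x", "y", "c")


class SingularSolveError(ArithmeticError):
    """F-subproblem is singular (gamma = 0 leaves the DC mode free)."""


class SolverDivergenceError(RuntimeError):
    """A non-finite value appeared during ADMM iteration."""


@dataclass
class SolverParams:
    """Parameters of the TV energy and its ADMM solver.

    Parameters
    ----------
    gamma : float
        Data-fidelity weight.  Small values give a smoother veil; large
        values pull the veil toward the input image.  All values are on
        the internal [0, 1] intensity scale.
    rho : float
        ADMM penalty parameter (> 0).  Also sets the shrinkage
        threshold ``1 / rho``.
    theta_x, theta_y, theta_c : float
        Direction weights of the isotropic TV norm: spatial smoothness
        (x, y) versus inter-channel similarity (c).
    eps : float
        Floor applied to the pointwise norm ``v`` inside the shrinkage
        step, and to denominators in relative-change tests.
    max_iters : int
        Iteration cap.
    tol : float
        Relative-change stopping threshold on F.
    """

    gamma: float = 1.0
    rho: float = 5.0
    theta_x: float = 1.0
    theta_y: float = 1.0
    theta_c: float = 1.0
    eps: float = 1e-6
    max_iters: int = 50
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if min(self.theta_x, self.theta_y, self.theta_c) < 0:
            raise ValueError("direction weights must be non-negative")
        if max(self.theta_x, self.theta_y, self.theta_c) == 0:
            raise ValueError("at least one direction weight must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")

    @property
    def thetas(self) -> dict[str, float]:
        return {"x": self.theta_x, "y": self.theta_y, "c": self.theta_c}


@dataclass
class ADMMState:
    """Splitting variable ``u`` and multipliers ``r`` per direction."""

    u_x: np.ndarray
    u_y: np.ndarray
    u_c: np.ndarray
    r_x: np.ndarray
    r_y: np.ndarray
    r_c: np.ndarray
    iteration: int = 0

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "ADMMState":
        return cls(*(np.zeros(shape) for _ in range(6)))

    @property
    def u(self) -> dict[str, np.ndarray]:
        return {"x": self.u_x, "y": self.u_y, "c": self.u_c}

    @property
    def r(self) -> dict[str, np.ndarray]:
        return {"x": self.r_x, "y": self.r_y, "c": self.r_c}


@dataclass
class SolverDiagnostics:
    """Per-run convergence record of :func:`estimate_smoke_veil`."""

    iterations: int
    converged: bool
    energy_trace: np.ndarray
    primal_residual_trace: np.ndarray
    final_relative_change: float

    @property
    def final_energy(self) -> float:
        return float(self.energy_trace[-1])

    @property
    def final_primal_residual(self) -> float:
        return float(self.primal_residual_trace[-1])


def forward_diff(F: np.ndarray, direction: str) -> np.ndarray:
    """Forward difference with circular wrap along ``direction``.

    ``Dx F(x, y, c) = F(x+1, y, c) - F(x, y, c)`` and analogously for
    y and c; the last index differences against the first.
    """
    axis = _AXIS[direction]
    return np.roll(F, -1, axis=axis) - F


def adjoint_diff(G: np.ndarray, direction: str) -> np.ndarray:
    """Adjoint ``D^T`` of the circular forward difference.

    Equals the negated circular backward difference:
    ``(D^T G)(x) = G(x-1) - G(x)``, so that ``<D F, G> = <F, D^T G>``
    exactly for every pair of fields.
    """
    axis = _AXIS[direction]
    return np.roll(G, 1, axis=axis) - G


def _weighted_diffs(F: np.ndarray, p: SolverParams) -> dict[str, np.ndarray]:
    return {d: p.thetas[d] * forward_diff(F, d) for d in _DIRECTIONS}


def isotropic_tv(
    F: np.ndarray, thetas: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> float:
    """Isotropic 3-D TV norm: sum_i ||(tx DxF, ty DyF, tc DcF)_i||_2."""
    tx, ty, tc = thetas
    sq = (
        (tx * forward_diff(F, "x")) ** 2
        + (ty * forward_diff(F, "y")) ** 2
        + (tc * forward_diff(F, "c")) ** 2
    )
    return float(np.sum(np.sqrt(sq)))


def energy(F: np.ndarray, I: np.ndarray, p: SolverParams) -> float:
    """TV energy of a candidate veil F given the degraded image I."""
    F = np.asarray(F, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if F.shape != I.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs I {I.shape}")
    data = 0.5 * p.gamma * float(np.sum((F - I) ** 2))
    tv = isotropic_tv(F, (p.theta_x, p.theta_y, p.theta_c))
    return data + tv


def _diff_gain_squared(n: int) -> np.ndarray:
    """|FFT transfer function|^2 of the circular forward difference.

    The length-n stencil has frequency response exp(2*pi*i*k/n) - 1,
    whose squared magnitude is 2 - 2*cos(2*pi*k/n).
    """
    omega = 2.0 * np.pi * np.fft.fftfreq(n)
    return 2.0 - 2.0 * np.cos(omega)


def solve_F_subproblem(
    I: np.ndarray, state: ADMMState, p: SolverParams
) -> np.ndarray:
    """Exact FFT solve of the quadratic F-subproblem.

    Solves ``(gamma + rho D^T D) F = gamma I + rho D^T u - D^T r`` under
    periodic boundaries by pointwise division in the 3-D Fourier domain.
    The imaginary residue of the inverse transform is discarded.
    """
    H, W, C = I.shape
    rhs = p.gamma * I
    for d in _DIRECTIONS:
        rhs = rhs + p.thetas[d] * adjoint_diff(
            p.rho * state.u[d] - state.r[d], d
        )

    den = p.gamma + p.rho * (
        p.theta_x**2 * _diff_gain_squared(W)[None, :, None]
        + p.theta_y**2 * _diff_gain_squared(H)[:, None, None]
        + p.theta_c**2 * _diff_gain_squared(C)[None, None, :]
    )
    if np.min(den) <= 0.0:
        raise SingularSolveError(
            "F-subproblem is singular: gamma = 0 leaves the constant "
            "(DC) component of F unconstrained"
        )
    F_hat = scipy.fft.fftn(rhs) / den
    return scipy.fft.ifftn(F_hat).real


def shrink_u(
    F: np.ndarray, state: ADMMState, p: SolverParams
) -> dict[str, np.ndarray]:
    """Isotropic vector soft-threshold (u-update).

    With ``v_d = theta_d * D_d F + r_d / rho`` and pointwise magnitude
    ``v = max(sqrt(v_x^2 + v_y^2 + v_c^2), eps)``, each direction gets
    ``u_d = max(v - 1/rho, 0) * v_d / v`` — the shrinkage couples the
    three directions through the shared norm ``v``.
    """
    v = {
        d: p.thetas[d] * forward_diff(F, d) + state.r[d] / p.rho
        for d in _DIRECTIONS
    }
    vnorm = np.sqrt(sum(v[d] ** 2 for d in _DIRECTIONS))
    vfloor = np.maximum(vnorm, p.eps)
    scale = np.maximum(vfloor - 1.0 / p.rho, 0.0) / vfloor
    return {d: scale * v[d] for d in _DIRECTIONS}


def update_multipliers(
    state: ADMMState, F: np.ndarray, p: SolverParams
) -> dict[str, np.ndarray]:
    """Multiplier ascent: ``r_d += rho * (theta_d D_d F - u_d)``."""
    return {
        d: state.r[d] + p.rho * (p.thetas[d] * forward_diff(F, d) - state.u[d])
        for d in _DIRECTIONS
    }


def _primal_residual(F: np.ndarray, state: ADMMState, p: SolverParams) -> float:
    sq = 0.0
    for d in _DIRECTIONS:
        sq += float(
            np.sum((p.thetas[d] * forward_diff(F, d) - state.u[d]) ** 2)
        )
    return float(np.sqrt(sq))


def estimate_smoke_veil(
    I: np.ndarray, p: SolverParams | None = None
) -> tuple[np.ndarray, SolverDiagnostics]:
    """Estimate the smoke veil F of a degraded image by ADMM.

    Initializes ``F = I``, ``u = r = 0`` and iterates F-update →
    u-update → r-update until the relative change of F falls below
    ``p.tol`` or ``p.max_iters`` is reached.  The returned veil is
    clipped to [0, 1]; iterates themselves are never clipped, since the
    F-subproblem is an unconstrained solve.

    Returns
    -------
    F : ndarray
        The estimated veil, same shape as ``I``, in [0, 1].
    diagnostics : SolverDiagnostics
        Iteration count, energy trace and primal-residual trace.
    """
    I = validate_image(I, "I")
    if p is None:
        p = SolverParams()

    F = I.copy()
    state = ADMMState.zeros(I.shape)
    energies = [energy(F, I, p)]
    residuals: list[float] = []
    converged = False
    rel = np.inf

    for k in range(p.max_iters):
        F_new = solve_F_subproblem(I, state, p)
        if not np.all(np.isfinite(F_new)):
            raise SolverDivergenceError(
                f"non-finite veil at iteration {k + 1}"
            )
        u = shrink_u(F_new, state, p)
        state.u_x, state.u_y, state.u_c = u["x"], u["y"], u["c"]
        r = update_multipliers(state, F_new, p)
        state.r_x, state.r_y, state.r_c = r["x"], r["y"], r["c"]
        state.iteration = k + 1

        energies.append(energy(F_new, I, p))
        residuals.append(_primal_residual(F_new, state, p))
        rel = float(
            np.linalg.norm(F_new - F) / max(np.linalg.norm(F), p.eps)
        )
        F = F_new
        if rel <= p.tol:
            converged = True
            break

    diagnostics = SolverDiagnostics(
        iterations=state.iteration,
        converged=converged,
        energy_trace=np.asarray(energies),
        primal_residual_trace=np.asarray(residuals),
        final_relative_change=rel,
    )
    return np.clip(F, 0.0, 1.0), diagnostics
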