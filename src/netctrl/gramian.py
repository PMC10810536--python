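"""Gramian-based controllability machinery.

Infinite-horizon controllability/observability Gramians are computed by
continuous Lyapunov solves (requiring Hurwitz dynamics); finite-horizon
Gramians by composite trapezoid quadrature or by the exact difference
identity ``W(t) = W - e^{At} W e^{A't}``.  Worst-case control energies are
``1 / lambda_min`` of the relevant (target-projected) Gramian, with a
practical-controllability threshold on the minimum eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .connectome import EffectiveConnectome, spectral_abscissa
from .errors import NotTargetControllableError, ParameterError, StabilityError

#: Eigenvalues below this threshold are treated as numerically zero.
EPSILON = 1e-12

_STABILITY_TOL = -1e-6


def _as_matrix(ec) -> np.ndarray:
    return ec.A if isinstance(ec, EffectiveConnectome) else np.asarray(ec, float)


def _require_stable(A: np.ndarray) -> None:
    if spectral_abscissa(A) > _STABILITY_TOL:
        raise StabilityError(
            "infinite-horizon Gramian requires a Hurwitz matrix "
            f"(spectral abscissa {spectral_abscissa(A):.3g})")


@dataclass(frozen=True)
class DriverSet:
    """Ordered distinct driver node indices with optional accessibility
    weights (defaults to 1 for every driver)."""

    indices: tuple[int, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ParameterError("driver set must be non-empty")
        if len(set(idx)) != len(idx):
            raise ParameterError("driver indices must be distinct")
        if any(i < 0 for i in idx):
            raise IndexError("driver indices must be non-negative")
        if self.weights is not None:
            w = tuple(float(v) for v in self.weights)
            object.__setattr__(self, "weights", w)
            if len(w) != len(idx):
                raise ParameterError("weights must match indices")
            if any(not 0 < v <= 1 for v in w):
                raise ParameterError("weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.indices)

    def b_matrix(self, n: int) -> np.ndarray:
        """Input matrix: one column per driver, weight at the driver row."""
        if max(self.indices) >= n:
            raise IndexError("driver index out of range")
        B = np.zeros((n, len(self.indices)))
        w = self.weights if self.weights is not None else (1.0,) * len(self)
        for col, (i, wi) in enumerate(zip(self.indices, w)):
            B[i, col] = wi
        return B


@dataclass(frozen=True)
class TargetSet:
    """Ordered distinct target node indices."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ParameterError("target set must be non-empty")
        if len(set(idx)) != len(idx):
            raise ParameterError("target indices must be distinct")
        if any(i < 0 for i in idx):
            raise IndexError("target indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def c_matrix(self, n: int) -> np.ndarray:
        if max(self.indices) >= n:
            raise IndexError("target index out of range")
        C = np.zeros((len(self.indices), n))
        for row, j in enumerate(self.indices):
            C[row, j] = 1.0
        return C


@dataclass(frozen=True)
class GramianResult:
    kind: str  # controllability | observability | target
    W: np.ndarray
    eigenvalues: np.ndarray
    lambda_min: float
    practically_controllable: bool
    epsilon: float = EPSILON
    method: str = "lyapunov"  # lyapunov | quadrature | finite_horizon
    horizon: float = np.inf


def _gramian_result(W: np.ndarray, kind: str, method: str = "lyapunov",
                    horizon: float = np.inf) -> GramianResult:
    W = 0.5 * (W + W.T)
    eig = np.sort(np.linalg.eigvalsh(W))
    lam = float(eig[0])
    return GramianResult(kind=kind, W=W, eigenvalues=eig, lambda_min=lam,
                         practically_controllable=lam > EPSILON,
                         method=method, horizon=horizon)


def controllability_gramian(ec, drivers: DriverSet) -> GramianResult:
    """Infinite-horizon controllability Gramian for the given driver set.

    Solves ``A W + W A' + B B' = 0``.
    """
    A = _as_matrix(ec)
    _require_stable(A)
    B = drivers.b_matrix(A.shape[0])
    W = solve_continuous_lyapunov(A, -B @ B.T)
    return _gramian_result(W, "controllability")


def gramian_from_input_matrix(ec, B: np.ndarray) -> GramianResult:
    """Controllability Gramian for an arbitrary input matrix ``B``
    (e.g. a single broadcast column of ones)."""
    A = _as_matrix(ec)
    _require_stable(A)
    B = np.atleast_2d(np.asarray(B, float))
    if B.shape[0] != A.shape[0]:
        B = B.T
    W = solve_continuous_lyapunov(A, -B @ B.T)
    return _gramian_result(W, "controllability")


def observability_gramian(ec, targets: TargetSet) -> GramianResult:
    """Infinite-horizon observability Gramian: ``A' M + M A + C' C = 0``."""
    A = _as_matrix(ec)
    _require_stable(A)
    C = targets.c_matrix(A.shape[0])
    M = solve_continuous_lyapunov(A.T, -C.T @ C)
    return _gramian_result(M, "observability")


def target_gramian(full: GramianResult, targets: TargetSet) -> GramianResult:
    """Project a full controllability Gramian on a target set: the principal
    submatrix on the target indices."""
    if full.kind != "controllability":
        raise ParameterError("target projection requires a controllability Gramian")
    idx = np.asarray(targets.indices)
    if idx.max() >= full.W.shape[0]:
        raise IndexError("target index out of range")
    Wc = full.W[np.ix_(idx, idx)]
    return _gramian_result(Wc, "target", method=full.method, horizon=full.horizon)


@dataclass(frozen=True)
class EnergyResult:
    energy: float
    log10_energy: float
    n_drivers: int
    n_targets: int
    basis: str = "worst_case"  # worst_case | pairwise | realized


def worst_case_energy(g: GramianResult, n_drivers: int = 0,
                      n_targets: int = 0) -> EnergyResult:
    """Worst-eigendirection control energy ``1 / lambda_min``; infinite when
    the Gramian is not practically positive definite."""
    if g.lambda_min > g.epsilon:
        e = 1.0 / g.lambda_min
        return EnergyResult(energy=e, log10_energy=float(np.log10(e)),
                            n_drivers=n_drivers, n_targets=n_targets)
    return EnergyResult(energy=np.inf, log10_energy=np.inf,
                        n_drivers=n_drivers, n_targets=n_targets)


@dataclass(frozen=True)
class PairwiseEnergyMatrix:
    """All single-driver -> single-target energies; entry ``E[i, j]`` is the
    energy to control target ``j`` through driver ``i`` (+inf if impossible)."""

    E: np.ndarray

    def __post_init__(self) -> None:
        E = np.asarray(self.E, float)
        object.__setattr__(self, "E", E)
        if np.any(E <= 0):
            raise ParameterError("pairwise energies must be positive")


def pairwise_energies(ec) -> PairwiseEnergyMatrix:
    """Compute every single-driver single-target energy with n Lyapunov solves.

    For driver ``i`` the Gramian diagonal gives all targets at once:
    ``E[i, j] = 1 / W^{(i)}_{jj}``.
    """
    A = _as_matrix(ec)
    _require_stable(A)
    n = A.shape[0]
    E = np.full((n, n), np.inf)
    for i in range(n):
        Q = np.zeros((n, n))
        Q[i, i] = -1.0
        Wi = solve_continuous_lyapunov(A, Q)
        d = np.diag(Wi).copy()
        good = d > 1e-300
        E[i, good] = 1.0 / d[good]
    return PairwiseEnergyMatrix(E=E)


def finite_horizon_gramian(ec, drivers: DriverSet, t_f: float,
                           dt: float) -> GramianResult:
    """Finite-horizon Gramian by composite trapezoid on a uniform grid.

    Monotone non-decreasing in ``t_f`` (PSD integrand) and converges to the
    Lyapunov solution for stable dynamics.
    """
    if dt >= t_f or dt <= 0:
        raise ParameterError("require 0 < dt < t_f")
    A = _as_matrix(ec)
    n = A.shape[0]
    B = drivers.b_matrix(n)
    times = np.arange(0.0, t_f + 0.5 * dt, dt)
    P = expm(A * dt)
    M = B.copy()  # e^{At} B at the current grid point
    W = np.zeros((n, n))
    for k in range(len(times)):
        wgt = 0.5 if k in (0, len(times) - 1) else 1.0
        W += wgt * (M @ M.T)
        M = P @ M
    W *= dt
    return _gramian_result(W, "controllability", method="finite_horizon",
                           horizon=float(times[-1]))


def _exact_finite_gramian(A: np.ndarray, B: np.ndarray, t_f: float) -> np.ndarray:
    """W(t_f) = W_inf - e^{A t_f} W_inf e^{A' t_f} for Hurwitz A (exact)."""
    Winf = solve_continuous_lyapunov(A, -B @ B.T)
    Phi = expm(A * t_f)
    W = Winf - Phi @ Winf @ Phi.T
    return 0.5 * (W + W.T)


@dataclass(frozen=True)
class ControlInput:
    """A control signal on a uniform grid together with its realized energy."""

    time_grid: np.ndarray
    u: np.ndarray  # (n_times, n_drivers)
    realized_energy: float
    x0: np.ndarray
    yf: np.ndarray
    predicted_energy: float = field(default=np.nan)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, float)
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "u", np.asarray(self.u, float))
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ParameterError("time grid must increase from 0")
        if self.realized_energy < 0:
            raise ParameterError("realized energy must be non-negative")


def min_energy_input(ec, drivers: DriverSet, targets: TargetSet,
                     x0: np.ndarray, yf: np.ndarray,
                     t_f: float = 50.0, dt: float | None = None) -> ControlInput:
    """Minimum-energy open-loop input steering the target outputs to ``yf``.

    ``u*(t) = B' e^{A'(t_f - t)} C' [C W(t_f) C']^{-1} (yf - C e^{A t_f} x0)``;
    the realized energy equals the quadratic form in the inverted target
    Gramian up to grid discretization.
    """
    A = _as_matrix(ec)
    _require_stable(A)
    n = A.shape[0]
    if dt is None:
        dt = t_f / 5000.0
    if dt >= t_f or dt <= 0:
        raise ParameterError("require 0 < dt < t_f")
    B = drivers.b_matrix(n)
    C = targets.c_matrix(n)
    x0 = np.asarray(x0, float)
    yf = np.asarray(yf, float)

    Wt = _exact_finite_gramian(A, B, t_f)
    Wc = C @ Wt @ C.T
    eig = np.linalg.eigvalsh(Wc)
    if eig[0] <= 0 or eig[-1] / eig[0] > 1e12:
        raise NotTargetControllableError(
            f"target Gramian numerically singular (lambda_min={eig[0]:.3g})",
            lambda_min=float(eig[0]))

    d = yf - C @ (expm(A * t_f) @ x0)
    alpha = np.linalg.solve(Wc, d)
    predicted = float(d @ alpha)

    times = np.arange(0.0, t_f + 0.5 * dt, dt)
    Q = expm(A.T * dt)
    v = expm(A.T * (t_f - times[-1])) @ (C.T @ alpha)
    u = np.empty((len(times), B.shape[1]))
    for k in range(len(times) - 1, -1, -1):
        u[k] = B.T @ v
        v = Q @ v
    realized = float(np.trapezoid(np.sum(u * u, axis=1), times))
    return ControlInput(time_grid=times, u=u, realized_energy=realized,
                        x0=x0, yf=yf, predicted_energy=predicted)


def simulate_controlled(ec, drivers: DriverSet, control: ControlInput,
                        x0: np.ndarray) -> np.ndarray:
    """Integrate ``x' = A x + B u`` with exact exponential stepping and
    piecewise-linear input between grid points.

    Uses the standard augmented-matrix discretization (one matrix exponential
    for the whole uniform grid).
    """
    A = _as_matrix(ec)
    n = A.shape[0]
    B = drivers.b_matrix(n)
    r = B.shape[1]
    t = control.time_grid
    u = control.u
    if u.shape != (len(t), r):
        raise ParameterError(
            f"input shape {u.shape} does not match grid x drivers ({len(t)}, {r})")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-9):
        raise ParameterError("grid must be uniform")
    h = float(steps[0])

    # Van Loan block: expm of [[A, B, 0], [0, 0, I], [0, 0, 0]] * h yields
    # Phi, G1 = int e^{A(h-s)}B ds, and G2 = int e^{A(h-s)}B s ds.
    F = np.zeros((n + 2 * r, n + 2 * r))
    F[:n, :n] = A
    F[:n, n:n + r] = B
    F[n:n + r, n + r:] = np.eye(r)
    E = expm(F * h)
    Phi = E[:n, :n]
    G1 = E[:n, n:n + r]
    G2 = E[:n, n + r:]

    traj = np.empty((len(t), n))
    x = np.asarray(x0, float).copy()
    for k in range(len(t) - 1):
        traj[k] = x
        slope = (u[k + 1] - u[k]) / h
        x = Phi @ x + G1 @ u[k] + G2 @ slope
    traj[-1] = x
    return traj
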