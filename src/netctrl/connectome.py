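"""Synthetic cohorts of signed, asymmetric effective-connectivity matrices.

The generative model produces stable (Hurwitz) coupling matrices sharing a
sparsity support within a cohort, with configurable link density, sign split
and inter-subject similarity, together with node metadata (resting-state
network labels, hemispheres, pseudo-anatomical coordinates), the stationary
functional connectivity implied by the linear stochastic dynamics, and
perturbed / accessibility-weighted variants used in sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov

from .errors import ParameterError, StabilityError

RSN_LABELS = ("CON", "DMN", "DAN", "LIM", "VAN", "SMN", "VIS", "SUB")

#: Default partition: 62 cortical + 12 subcortical regions.
DEFAULT_RSN_SIZES: Mapping[str, int] = {
    "CON": 10, "DMN": 16, "DAN": 9, "LIM": 5,
    "VAN": 11, "SMN": 6, "VIS": 5, "SUB": 12,
}

# Fixed seed for node coordinates so that a given partition always maps to the
# same pseudo-anatomical layout, independent of the cohort seed.
_COORD_SEED = 20230917

# Off-diagonal magnitudes: lognormal(mu, sigma) gives the heavy-tailed hub
# structure the downstream centrality analyses rely on.
_LOGNORMAL_MU = -1.5
_LOGNORMAL_SIGMA = 0.7


def spectral_abscissa(A: np.ndarray) -> float:
    """Maximum real part of the eigenvalues of ``A``."""
    return float(np.max(np.real(np.linalg.eigvals(A))))


@dataclass(frozen=True)
class NodeTable:
    """Node metadata: names, resting-state-network labels, hemispheres and
    3-D coordinates, indexed by a contiguous 0-based ``node_id``."""

    frame: pd.DataFrame

    _COLUMNS = ("node_id", "name", "rsn", "hemisphere", "x", "y", "z")

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(self._COLUMNS) - set(df.columns)
        if missing:
            raise ParameterError(f"node table missing columns: {sorted(missing)}")
        ids = df["node_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(df))):
            raise ParameterError("node_ids must be unique and contiguous from 0")
        bad = set(df["rsn"]) - set(RSN_LABELS)
        if bad:
            raise ParameterError(f"unknown RSN labels: {sorted(bad)}")
        if not set(df["hemisphere"]).issubset({"L", "R", "M"}):
            raise ParameterError("hemisphere must be one of L, R, M")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def rsn(self) -> np.ndarray:
        return self.frame["rsn"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y", "z"]].to_numpy(dtype=float)

    def indices_of(self, rsn: str) -> np.ndarray:
        """Node indices belonging to one RSN."""
        return np.flatnonzero(self.rsn == rsn)

    def rsn_sizes(self) -> dict[str, int]:
        return {lab: int(np.sum(self.rsn == lab)) for lab in RSN_LABELS
                if np.any(self.rsn == lab)}


@dataclass(frozen=True)
class EffectiveConnectome:
    """One subject's signed asymmetric coupling matrix.

    ``A[i, j]`` is the directed influence of node ``j`` on node ``i``, in
    units of inverse sampling intervals.  The matrix must be Hurwitz with a
    strictly negative diagonal.
    """

    A: np.ndarray
    nodes: NodeTable
    subject_id: str = "subject"
    tr_seconds: float = 1.4

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ParameterError(f"A must be square, got shape {A.shape}")
        if len(self.nodes) != A.shape[0]:
            raise ParameterError("node table size does not match matrix")
        if not np.all(np.isfinite(A)):
            raise ParameterError("A contains non-finite entries")
        if np.any(np.diag(A) >= 0):
            raise ParameterError("diagonal entries must be strictly negative")
        if spectral_abscissa(A) >= 0:
            raise StabilityError("A is not Hurwitz")

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class FunctionalConnectome:
    """Stationary covariance and correlation implied by the linear dynamics."""

    F: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        F, S = np.asarray(self.F, float), np.asarray(self.sigma, float)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "sigma", S)
        if not np.allclose(F, F.T, atol=1e-8):
            raise ParameterError("F must be symmetric")
        if not np.allclose(np.diag(F), 1.0, atol=1e-8):
            raise ParameterError("F must have unit diagonal")
        if np.any(np.abs(F) > 1 + 1e-8):
            raise ParameterError("F entries must lie in [-1, 1]")


@dataclass(frozen=True)
class AccessibilityVector:
    """Per-node input attenuation factors, each in (0, 1]."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", b)
        if b.ndim != 1 or np.any(b <= 0) or np.any(b > 1):
            raise ParameterError("accessibilities must lie in (0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_nodes: int = 74
    rsn_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RSN_SIZES))
    density: float = 0.39
    positive_fraction: float = 0.60
    intersubject_mix: float = 0.5
    stability_margin: float = 0.05
    noise_variance: float = 1.0
    n_subjects: int = 20
    seed: int = 0
    tr_seconds: float = 1.4

    def __post_init__(self) -> None:
        for name in ("density", "positive_fraction", "intersubject_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.stability_margin <= 0:
            raise ParameterError("stability_margin must be positive")
        if self.noise_variance <= 0:
            raise ParameterError("noise_variance must be positive")
        if self.n_subjects < 1 or self.n_nodes < 1:
            raise ParameterError("n_nodes and n_subjects must be positive")
        if sum(self.rsn_sizes.values()) != self.n_nodes:
            raise ParameterError("rsn_sizes must sum to n_nodes")
        if set(self.rsn_sizes) - set(RSN_LABELS):
            raise ParameterError("rsn_sizes keys must be RSN labels")
        if self.density == 0.0 and self.positive_fraction > 0.0:
            raise ParameterError(
                "density 0 admits no links; positive_fraction is meaningless")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rsn_sizes"] = dict(d["rsn_sizes"])
        return d


@dataclass(frozen=True)
class Cohort:
    """Ordered list of subjects sharing one node table."""

    subjects: tuple[EffectiveConnectome, ...]
    nodes: NodeTable
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        for s in self.subjects:
            if s.nodes.frame is not self.nodes.frame and len(s.nodes) != len(self.nodes):
                raise ParameterError("subjects must share the cohort node table")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# node metadata


def make_node_table(rsn_sizes: Mapping[str, int]) -> NodeTable:
    """Deterministic node table for a given RSN partition.

    Coordinates are RSN-clustered Gaussian blobs around fixed per-network
    centres (fixed internal seed), so spatial-gradient analyses are
    executable on synthetic data without pretending to be anatomy.
    """
    rng = np.random.default_rng(_COORD_SEED)
    centers = {lab: rng.uniform(-60, 60, size=3) for lab in RSN_LABELS}
    rows = []
    node_id = 0
    for lab in RSN_LABELS:
        count = int(rsn_sizes.get(lab, 0))
        for k in range(count):
            hemi = "M" if lab == "SUB" and k >= count - 2 else ("L", "R")[k % 2]
            xyz = centers[lab] + rng.normal(scale=8.0, size=3)
            rows.append((node_id, f"{lab}_{k}", lab, hemi, *np.round(xyz, 2)))
            node_id += 1
    frame = pd.DataFrame(rows, columns=list(NodeTable._COLUMNS))
    return NodeTable(frame)


# ---------------------------------------------------------------------------
# stability


def ensure_stable(A: np.ndarray, margin: float) -> np.ndarray:
    """Uniformly shift the diagonal so the spectral abscissa is exactly
    ``-margin``.

    The shift ``c*I`` moves every eigenvalue by the same real amount, so the
    result is the closest diagonal-shift stabilisation; applying the function
    twice is a no-op.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ParameterError(f"expected a square matrix, got shape {A.shape}")
    if margin <= 0:
        raise ParameterError("margin must be positive")
    shift = -margin - spectral_abscissa(A)
    return A + shift * np.eye(A.shape[0])


# ---------------------------------------------------------------------------
# generation


def _draw_signed_weights(rng: np.random.Generator, support: np.ndarray,
                         positive_fraction: float, n: int) -> np.ndarray:
    """Signed lognormal off-diagonal weights on a fixed support, with a fresh
    random diagonal in [-1, -0.5]."""
    M = np.zeros((n, n))
    k = int(support.sum())
    mags = rng.lognormal(_LOGNORMAL_MU, _LOGNORMAL_SIGMA, size=k)
    signs = np.where(rng.random(k) < positive_fraction, 1.0, -1.0)
    M[support] = mags * signs
    M[np.diag_indices(n)] = -(0.5 + rng.uniform(0, 0.5, size=n))
    return M


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort of stable EC matrices sharing one sparsity support.

    Each subject is the convex mixture ``rho * base + (1 - rho) * noise`` of a
    cohort-level base matrix and an independent subject draw on the same
    support (``rho = intersubject_mix``), then diagonally shifted to spectral
    abscissa ``-stability_margin``.  Identical seeds give bit-identical
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    offdiag = ~np.eye(n, dtype=bool)
    support = np.zeros((n, n), dtype=bool)
    support[offdiag] = rng.random(n * (n - 1)) < config.density

    base = _draw_signed_weights(rng, support, config.positive_fraction, n)
    nodes = make_node_table(config.rsn_sizes)
    rho = config.intersubject_mix

    subjects = []
    for s in range(config.n_subjects):
        noise = _draw_signed_weights(rng, support, config.positive_fraction, n)
        A = rho * base + (1.0 - rho) * noise
        A = ensure_stable(A, config.stability_margin)
        subjects.append(EffectiveConnectome(
            A=A, nodes=nodes, subject_id=f"sub-{s:03d}",
            tr_seconds=config.tr_seconds))
    return Cohort(subjects=tuple(subjects), nodes=nodes, config=config)


def intersubject_correlation(cohort: Cohort) -> float:
    """Mean pairwise Pearson correlation of the vectorized off-diagonal
    coupling entries.

    The diagonal is excluded: it carries the uniform stabilizing shift, a
    structure common to all subjects that would otherwise put a floor under
    the correlation regardless of the mixing weight.
    """
    off = ~np.eye(cohort.n, dtype=bool)
    mats = [s.A[off] for s in cohort.subjects]
    corrs = []
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            corrs.append(np.corrcoef(mats[i], mats[j])[0, 1])
    if not corrs:
        raise ParameterError("need at least two subjects")
    return float(np.mean(corrs))


def calibrate_intersubject_mix(config: GeneratorConfig,
                               target_correlation: float = 0.49,
                               tol: float = 0.01,
                               max_iter: int = 30) -> float:
    """Bisect the mixing weight so the generated cohort hits a target mean
    inter-subject correlation.

    The correlation is monotone increasing in the mixing weight (0 gives
    near-independent subjects, 1 identical ones), so plain bisection on
    cohorts generated at the config seed converges quickly.
    """
    if not 0.0 < target_correlation < 1.0:
        raise ParameterError("target correlation must be in (0, 1)")

    def realized(rho: float) -> float:
        cfg = dataclasses.replace(config, intersubject_mix=rho)
        return intersubject_correlation(generate_cohort(cfg))

    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = realized(mid)
        if abs(r - target_correlation) < tol:
            return mid
        if r < target_correlation:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# derived functional connectivity and free dynamics


def stationary_fc(ec: EffectiveConnectome, sigma2: float = 1.0) -> FunctionalConnectome:
    """Stationary covariance and correlation of ``dx = A x dt + sigma dW``.

    Solves ``A S + S A' + sigma2 I = 0``; the correlation matrix is obtained
    by symmetric diagonal normalization.  Correlations are invariant to
    ``sigma2`` under this model.
    """
    if sigma2 <= 0:
        raise ParameterError("sigma2 must be positive")
    A = ec.A
    if spectral_abscissa(A) >= -1e-9:
        raise StabilityError("stationary covariance undefined for unstable A")
    S = solve_continuous_lyapunov(A, -sigma2 * np.eye(ec.n))
    S = 0.5 * (S + S.T)
    d = np.sqrt(np.diag(S))
    F = S / np.outer(d, d)
    F = np.clip(0.5 * (F + F.T), -1.0, 1.0)
    np.fill_diagonal(F, 1.0)
    return FunctionalConnectome(F=F, sigma=S)


def simulate_free_response(ec: EffectiveConnectome, source: int,
                           t_max: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Impulse response ``exp(A t) e_source`` on a uniform grid.

    Returns ``(times, trajectory)`` with ``trajectory[k]`` the state at
    ``times[k]``; propagation uses one matrix exponential per step size.
    """
    if not 0 < dt < t_max:
        raise ParameterError("require 0 < dt < t_max")
    if not 0 <= source < ec.n:
        raise IndexError(f"source index {source} out of range")
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    P = expm(ec.A * dt)
    traj = np.empty((len(times), ec.n))
    x = np.zeros(ec.n)
    x[source] = 1.0
    for k in range(len(times)):
        traj[k] = x
        x = P @ x
    return times, traj


def peak_response_times(ec: EffectiveConnectome, t_max: float,
                        dt: float) -> np.ndarray:
    """Time of the maximal absolute impulse response for every ordered pair.

    Entry ``(j, i)`` is the grid time maximising ``|[exp(A t)]_{ji}|`` (the
    response at ``j`` to a unit impulse at ``i``).  The diagonal, and pairs
    with identically zero response, are NaN.
    """
    if not 0 < dt < t_max:
        raise ParameterError("require 0 < dt < t_max")
    n = ec.n
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    P = expm(ec.A * dt)
    M = np.eye(n)
    best = np.zeros((n, n))
    argbest = np.zeros((n, n))
    for t in times:
        absM = np.abs(M)
        improved = absM > best
        best[improved] = absM[improved]
        argbest[improved] = t
        M = P @ M
    out = argbest.copy()
    out[best <= 0.0] = np.nan
    np.fill_diagonal(out, np.nan)
    return out


# ---------------------------------------------------------------------------
# perturbation and accessibility


def perturb_connectome(ec: EffectiveConnectome, f: float,
                       seed: int | np.random.Generator = 0) -> EffectiveConnectome:
    """Add entrywise Gaussian noise with std ``f * |A_ij|`` to every nonzero
    entry (zeros stay exactly zero, so the support is preserved).

    ``f = 0`` returns the input matrix unchanged.  The result is re-stabilized
    by a diagonal shift only if the noise made it unstable.
    """
    if f < 0:
        raise ParameterError("noise level f must be non-negative")
    A = ec.A.copy()
    if f > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        nz = A != 0.0
        A[nz] = A[nz] + rng.normal(0.0, f * np.abs(A[nz]))
        if spectral_abscissa(A) >= 0:
            A = ensure_stable(A, -spectral_abscissa(ec.A))
        if np.any(np.diag(A) >= 0):  # keep the diagonal-sign invariant
            A[np.diag_indices(ec.n)] = np.minimum(np.diag(A), -1e-6)
    return EffectiveConnectome(A=A, nodes=ec.nodes,
                               subject_id=ec.subject_id + f"+f{f}",
                               tr_seconds=ec.tr_seconds)


def sample_accessibility(n: int, lo: float = 0.01, hi: float = 1.0,
                         seed: int | np.random.Generator = 0) -> AccessibilityVector:
    """Independent uniform accessibilities on ``[lo, hi]``, reproducible by seed."""
    if not 0 < lo <= hi <= 1:
        raise ParameterError("require 0 < lo <= hi <= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return AccessibilityVector(beta=rng.uniform(lo, hi, size=n))


# ---------------------------------------------------------------------------
# realized cohort statistics (used by calibration tests and reports)


def realized_density(ec: EffectiveConnectome) -> float:
    off = ~np.eye(ec.n, dtype=bool)
    return float(np.mean(ec.A[off] != 0.0))


def realized_positive_fraction(ec: EffectiveConnectome) -> float:
    off = ~np.eye(ec.n, dtype=bool)
    vals = ec.A[off]
    nz = vals[vals != 0.0]
    if nz.size == 0:
        return float("nan")
    return float(np.mean(nz > 0))
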