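"""Driver-node ranking, selection, baselines and group-level statistics.

Includes deterministic centrality rankings with an explicit tie rule, random
driver baselines, per-target-set optimal-centrality identification, mean-rank
aggregation across subjects, and Fisher-exact enrichment of optimal driver
sets in network partitions with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata
from statsmodels.stats.multitest import multipletests

from .centrality import CENTRALITY_DIRECTIONS, compute_centrality
from .connectome import AccessibilityVector, Cohort
from .errors import ParameterError
from .gramian import (DriverSet, TargetSet, controllability_gramian,
                      pairwise_energies, target_gramian, worst_case_energy)

DEFAULT_CANDIDATES = ("driver_energy", "out_strength", "pq", "ratio", "pagerank")


@dataclass(frozen=True)
class Ranking:
    """A permutation of eligible nodes, best candidate first."""

    order: tuple[int, ...]
    scores: np.ndarray  # aligned with ``order``
    centrality_name: str = ""
    direction: str = "descending"
    tie_rule: str = "node_id"

    def __post_init__(self) -> None:
        object.__setattr__(self, "order", tuple(int(i) for i in self.order))
        object.__setattr__(self, "scores", np.asarray(self.scores, float))
        if len(set(self.order)) != len(self.order):
            raise ParameterError("ranking order must be a permutation")
        if len(self.scores) != len(self.order):
            raise ParameterError("scores must align with order")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> tuple[int, ...]:
        return self.order[:k]

    def positions(self) -> dict[int, float]:
        """1-based fractional rank positions (ties share their mean position)."""
        key = self.scores if self.direction == "ascending" else -self.scores
        # +inf scores sit past every finite key in either direction
        key = np.where(np.isinf(self.scores), np.inf, key)
        pos = rankdata(key, method="average")
        return {node: float(p) for node, p in zip(self.order, pos)}


def rank_nodes(scores: np.ndarray, direction: str = "descending",
               eligible: np.ndarray | None = None,
               centrality_name: str = "") -> Ranking:
    """Stable sort of eligible nodes by score.

    ``+inf`` scores are always placed last regardless of direction; ties are
    broken by ascending node id.
    """
    scores = np.asarray(scores, float)
    if direction not in ("ascending", "descending"):
        raise ParameterError("direction must be ascending or descending")
    if eligible is None:
        eligible = np.arange(len(scores))
    eligible = np.asarray(sorted(int(i) for i in eligible))
    if eligible.size == 0:
        raise ParameterError("eligible set must be non-empty")
    sub = scores[eligible]
    key = sub if direction == "ascending" else -sub
    key = np.where(np.isinf(sub), np.inf, key)
    idx = np.lexsort((eligible, key))  # stable: ties fall back to node_id
    order = eligible[idx]
    return Ranking(order=tuple(order), scores=sub[idx],
                   centrality_name=centrality_name, direction=direction)


def select_drivers(ranking: Ranking, n_d: int,
                   exclude: TargetSet | None = None) -> DriverSet:
    """First ``n_d`` ranked nodes outside the excluded set."""
    banned = set(exclude.indices) if exclude is not None else set()
    chosen = [i for i in ranking.order if i not in banned][:n_d]
    if len(chosen) < n_d:
        raise ParameterError(
            f"cannot select {n_d} drivers from {len(ranking) - len(banned)} eligible nodes")
    return DriverSet(indices=tuple(chosen))


def random_driver_sets(n: int, n_d: int, exclude: TargetSet | None = None,
                       M: int = 100,
                       seed: int | np.random.Generator = 0) -> list[DriverSet]:
    """M uniform driver sets sampled without replacement from the eligible nodes."""
    banned = set(exclude.indices) if exclude is not None else set()
    eligible = np.array([i for i in range(n) if i not in banned])
    if n_d > eligible.size or n_d < 1 or M < 1:
        raise ParameterError("infeasible random driver-set request")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return [DriverSet(indices=tuple(sorted(rng.choice(eligible, n_d, replace=False))))
            for _ in range(M)]


def zscore_vs_random(value: float, random_values: np.ndarray) -> float:
    """Standard score of ``value`` against a random baseline sample
    (sd with denominator M - 1)."""
    rv = np.asarray(random_values, float)
    if rv.size < 2:
        raise ParameterError("need at least two baseline values")
    sd = float(np.std(rv, ddof=1))
    if sd == 0:
        raise ParameterError("baseline has zero spread; z-score undefined")
    return (float(value) - float(np.mean(rv))) / sd


def _target_energy(ec, drivers: DriverSet, targets: TargetSet) -> float:
    g = controllability_gramian(ec, drivers)
    return worst_case_energy(target_gramian(g, targets),
                             n_drivers=len(drivers), n_targets=len(targets)
                             ).log10_energy


@dataclass(frozen=True)
class SelectionResult:
    target_set: TargetSet
    centrality_name: str
    drivers_per_subject: tuple[DriverSet, ...]
    log10_energies: np.ndarray
    mean_log10_energy: float


def subject_rankings(cohort: Cohort, centrality_name: str,
                     eligible: np.ndarray | None = None,
                     fcs=None, pes=None,
                     accessibility: AccessibilityVector | None = None
                     ) -> list[Ranking]:
    """Per-subject rankings by one centrality (cached inputs optional)."""
    direction = CENTRALITY_DIRECTIONS[centrality_name]
    rankings = []
    for s, ec in enumerate(cohort):
        fc = fcs[s] if fcs is not None else None
        pe = pes[s] if pes is not None else None
        scores = compute_centrality(ec, centrality_name, fc=fc, pe=pe,
                                    accessibility=accessibility)
        rankings.append(rank_nodes(scores, direction, eligible, centrality_name))
    return rankings


def evaluate_selection(cohort: Cohort, rankings: list[Ranking], n_d: int,
                       targets: TargetSet, name: str = "") -> SelectionResult:
    """Energy of ranking-based driver selection, one driver set per subject."""
    drivers, energies = [], []
    for ec, r in zip(cohort, rankings):
        d = select_drivers(r, n_d, exclude=targets)
        drivers.append(d)
        energies.append(_target_energy(ec, d, targets))
    energies = np.asarray(energies)
    finite = energies[np.isfinite(energies)]
    mean = float(np.mean(finite)) if finite.size else np.inf
    return SelectionResult(target_set=targets, centrality_name=name,
                           drivers_per_subject=tuple(drivers),
                           log10_energies=energies, mean_log10_energy=mean)


def optimal_centrality(cohort: Cohort, targets: TargetSet,
                       candidates=DEFAULT_CANDIDATES, n_d: int = 10,
                       pes=None, fcs=None):
    """Identify the candidate centrality minimizing the cohort-mean log10
    target-control energy; returns ``(best_name, {name: SelectionResult})``."""
    if not candidates:
        raise ParameterError("candidate list must be non-empty")
    if pes is None and any(c in ("driver_energy", "target_energy") for c in candidates):
        pes = [pairwise_energies(ec) for ec in cohort]
    results = {}
    for name in candidates:
        rankings = subject_rankings(cohort, name, fcs=fcs, pes=pes)
        results[name] = evaluate_selection(cohort, rankings, n_d, targets, name)
    means = {k: v.mean_log10_energy for k, v in results.items()}
    if all(np.isinf(v) for v in means.values()):
        warnings.warn("all candidates yield infinite energy for every subject")
    best = min(means, key=lambda k: means[k])
    return best, results


def aggregate_ranks(rankings: list[Ranking]) -> Ranking:
    """Group ranking by per-node mean of 1-based rank positions.

    Ties in the aggregated mean rank fall back to ascending node id.
    """
    if not rankings:
        raise ParameterError("need at least one ranking")
    nodes = sorted(rankings[0].order)
    for r in rankings[1:]:
        if sorted(r.order) != nodes:
            raise ParameterError("rankings must cover the same eligible set")
    nodes = np.asarray(nodes)
    mean_pos = np.zeros(len(nodes))
    for r in rankings:
        pos = r.positions()
        mean_pos += np.array([pos[i] for i in nodes])
    mean_pos /= len(rankings)
    return rank_nodes(_dense_scores(nodes, mean_pos), "ascending", nodes,
                      centrality_name="aggregated")


def _dense_scores(nodes: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.full(int(nodes.max()) + 1, np.inf)
    out[nodes] = values
    return out


@dataclass(frozen=True)
class EnrichmentRow:
    driver_rsn: str
    target_rsn: str
    n1: int
    n2: int
    n3: int
    n4: int
    odds_ratio: float
    p_value: float
    mean_top_count: float
    q_value: float = np.nan
    marker: str = "none"
    degenerate: bool = False


def enrichment_test(optimal_sets: list[set[int]], node_rsn: np.ndarray,
                    driver_rsn: str, target_rsn: str) -> EnrichmentRow:
    """Fisher exact test for over/under-representation of a driver RSN among
    per-subject optimal driver sets (target-RSN nodes excluded throughout).

    n1/n3 count optimal/non-optimal nodes inside the driver RSN, n2/n4
    outside; two-sided p-value on the 2x2 table.
    """
    node_rsn = np.asarray(node_rsn)
    eligible = set(np.flatnonzero(node_rsn != target_rsn).tolist())
    D = set(np.flatnonzero(node_rsn == driver_rsn).tolist()) & eligible
    n1 = n2 = n3 = n4 = 0
    for O in optimal_sets:
        O = set(O) & eligible
        comp = eligible - O
        n1 += len(O & D)
        n2 += len(O - D)
        n3 += len(comp & D)
        n4 += len(comp - D)
    table = np.array([[n1, n2], [n3, n4]])
    degenerate = bool(np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0))
    if degenerate:
        odds, p = np.nan, 1.0
    else:
        odds, p = fisher_exact(table, alternative="two-sided")
    mean_top = n1 / len(optimal_sets) if optimal_sets else np.nan
    return EnrichmentRow(driver_rsn=driver_rsn, target_rsn=target_rsn,
                         n1=n1, n2=n2, n3=n3, n4=n4,
                         odds_ratio=float(odds), p_value=float(p),
                         mean_top_count=mean_top, degenerate=degenerate)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mark_enrichment(rows: list[EnrichmentRow],
                    alpha: float = 0.05) -> list[EnrichmentRow]:
    """Attach BH-adjusted q-values and +/- significance markers."""
    q = fdr_adjust([r.p_value for r in rows])
    out = []
    for r, qv in zip(rows, q):
        marker = "none"
        if qv < alpha and not r.degenerate and not np.isnan(r.odds_ratio):
            marker = "+" if r.odds_ratio > 1 else "-"  # inf odds counts as over
        out.append(replace(r, q_value=float(qv), marker=marker))
    return out


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def top_k_overlap(r1: Ranking, r2: Ranking, k: int = 10) -> float:
    """Fraction of shared nodes among the two top-k sets."""
    if k <= 0:
        raise ParameterError("k must be positive")
    if k > len(r1) or k > len(r2):
        raise ParameterError("k exceeds ranking size")
    return len(set(r1.top(k)) & set(r2.top(k))) / k
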