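"""End-to-end analyses on a cohort: energy scaling, pairwise-energy
correlates, hub statistics, per-RSN control tables, enrichment matrices,
perturbation sensitivity and accessibility experiments.

Energies are summarized on the log10 scale throughout; infinite energies are
kept in distributions (medians tolerate them) but excluded from means.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr

from . import __version__
from .centrality import (CENTRALITY_DIRECTIONS, compute_centrality,
                         propagator_coupling, shortest_paths)
from .connectome import (AccessibilityVector, Cohort, GeneratorConfig,
                         generate_cohort, perturb_connectome,
                         sample_accessibility, stationary_fc)
from .errors import ParameterError
from .gramian import (DriverSet, TargetSet, controllability_gramian,
                      pairwise_energies, target_gramian, worst_case_energy)
from .selection import (DEFAULT_CANDIDATES, aggregate_ranks, enrichment_table,
                        enrichment_test, evaluate_selection, mark_enrichment,
                        optimal_centrality, random_driver_sets, rank_nodes,
                        select_drivers, subject_rankings, top_k_overlap,
                        zscore_vs_random)

log = logging.getLogger("netctrl")


def fold_change(delta_log10: float) -> float:
    """Convert a difference of mean log10 energies to a multiplicative factor."""
    return float(10.0 ** delta_log10)


def horizon_seconds(T: float, tr_seconds: float) -> float:
    """Physical duration of a propagator horizon measured in sampling intervals."""
    return float(T) * float(tr_seconds)


@dataclass(frozen=True)
class ExperimentConfig:
    T: float = 10.0
    n_d_grid: tuple[int, ...] = (2, 5, 10, 20)
    n_t_grid: tuple[int, ...] = (2, 5, 10, 20, 40)
    n_d_fixed: int = 5
    M: int = 100
    k: int = 10
    f_grid: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
    n_sensitivity_reps: int = 10
    seed: int = 0
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ParameterError("T must be positive")
        for name in ("n_d_grid", "n_t_grid", "f_grid"):
            if len(getattr(self, name)) == 0:
                raise ParameterError(f"{name} must be non-empty")
        if min(self.n_d_grid) < 1 or min(self.n_t_grid) < 1:
            raise ParameterError("grids must be positive")


@dataclass(frozen=True)
class ScalingCurve:
    abscissa: tuple[int, ...]
    table: pd.DataFrame          # long form: x, selection, subject, log10_energy
    zscores: pd.DataFrame        # x, selection, subject, z
    summary: pd.DataFrame        # x, selection, median/mean log10 energy
    slope: float = np.nan


def _finite_mean(v: np.ndarray) -> float:
    v = np.asarray(v, float)
    f = v[np.isfinite(v)]
    return float(np.mean(f)) if f.size else np.inf


def _subject_caches(cohort: Cohort, candidates, config: ExperimentConfig,
                    need_pe: bool | None = None, need_fc: bool = False):
    need_pe = (need_pe if need_pe is not None
               else any(c in ("driver_energy", "target_energy") for c in candidates))
    pes = [pairwise_energies(ec) for ec in cohort] if need_pe else None
    fcs = ([stationary_fc(ec, config.sigma2) for ec in cohort]
           if need_fc or "fc_strength" in candidates else None)
    return pes, fcs


def scaling_vs_drivers(cohort: Cohort, config: ExperimentConfig,
                       accessibility: AccessibilityVector | None = None,
                       candidates: tuple[str, ...] | None = None) -> ScalingCurve:
    """Whole-network worst-case energy vs number of drivers, for
    centrality-based selections plus a random baseline of M draws."""
    candidates = candidates if candidates is not None else config.candidates
    n = cohort.n
    targets = TargetSet(indices=tuple(range(n)))
    pes, fcs = _subject_caches(cohort, candidates, config)
    rng = np.random.default_rng(config.seed)
    weights = None if accessibility is None else accessibility.beta

    rows, zrows = [], []
    rankings_by_name = {name: subject_rankings(cohort, name, pes=pes, fcs=fcs,
                                               accessibility=accessibility)
                        for name in candidates}
    for s, ec in enumerate(cohort):
        rand_sets = {n_d: random_driver_sets(n, n_d, M=config.M, seed=rng)
                     for n_d in config.n_d_grid}
        for n_d in config.n_d_grid:
            rand_e = np.array([_weighted_energy(ec, ds, targets, weights)
                               for ds in rand_sets[n_d]])
            rows += [{"x": n_d, "selection": "random", "subject": s,
                      "log10_energy": e} for e in rand_e]
            for name in candidates:
                ds = select_drivers(rankings_by_name[name][s], n_d)
                e = _weighted_energy(ec, ds, targets, weights)
                rows.append({"x": n_d, "selection": name, "subject": s,
                             "log10_energy": e})
                fin = rand_e[np.isfinite(rand_e)]
                if np.isfinite(e) and fin.size >= 2 and np.std(fin, ddof=1) > 0:
                    zrows.append({"x": n_d, "selection": name, "subject": s,
                                  "z": zscore_vs_random(e, fin)})
    table = pd.DataFrame(rows)
    summary = (table.groupby(["x", "selection"])["log10_energy"]
               .agg(["median", _finite_mean]).reset_index()
               .rename(columns={"_finite_mean": "mean"}))
    return ScalingCurve(abscissa=tuple(config.n_d_grid), table=table,
                        zscores=pd.DataFrame(zrows), summary=summary)


def _weighted_energy(ec, drivers: DriverSet, targets: TargetSet,
                     beta: np.ndarray | None) -> float:
    if beta is not None:
        drivers = DriverSet(indices=drivers.indices,
                            weights=tuple(beta[list(drivers.indices)]))
    g = controllability_gramian(ec, drivers)
    return worst_case_energy(target_gramian(g, targets)).log10_energy


def scaling_vs_targets(cohort: Cohort, config: ExperimentConfig,
                       mode: str = "random", rsn: str | None = None) -> ScalingCurve:
    """Energy vs number of targets for fixed drivers: nested random target
    prefixes, or nested growth within one RSN."""
    if mode not in ("random", "within_rsn"):
        raise ParameterError("mode must be 'random' or 'within_rsn'")
    n = cohort.n
    rng = np.random.default_rng(config.seed)
    if mode == "within_rsn":
        if rsn is None:
            raise ParameterError("within_rsn mode requires an RSN label")
        pool = cohort.nodes.indices_of(rsn)
        if pool.size == 0:
            raise ParameterError(f"no nodes in RSN {rsn}")
    else:
        pool = np.arange(n)
    sorted_pool = rng.permutation(pool)
    grid = tuple(x for x in config.n_t_grid if x <= len(sorted_pool))

    candidates = config.candidates
    pes, fcs = _subject_caches(cohort, candidates, config)
    rankings_by_name = {name: subject_rankings(cohort, name, pes=pes, fcs=fcs)
                        for name in candidates}
    rows, zrows = [], []
    for s, ec in enumerate(cohort):
        rand_sets = random_driver_sets(n, config.n_d_fixed, M=config.M, seed=rng)
        gram_rand = [controllability_gramian(ec, ds) for ds in rand_sets]
        gram_cent = {}
        for name in candidates:
            ds = select_drivers(rankings_by_name[name][s], config.n_d_fixed)
            gram_cent[name] = controllability_gramian(ec, ds)
        for n_t in grid:
            targets = TargetSet(indices=tuple(int(i) for i in sorted_pool[:n_t]))
            rand_e = np.array([worst_case_energy(target_gramian(g, targets)).log10_energy
                               for g in gram_rand])
            rows += [{"x": n_t, "selection": "random", "subject": s,
                      "log10_energy": e} for e in rand_e]
            for name in candidates:
                e = worst_case_energy(
                    target_gramian(gram_cent[name], targets)).log10_energy
                rows.append({"x": n_t, "selection": name, "subject": s,
                             "log10_energy": e})
                fin = rand_e[np.isfinite(rand_e)]
                if np.isfinite(e) and fin.size >= 2 and np.std(fin, ddof=1) > 0:
                    zrows.append({"x": n_t, "selection": name, "subject": s,
                                  "z": zscore_vs_random(e, fin)})
    table = pd.DataFrame(rows)
    summary = (table.groupby(["x", "selection"])["log10_energy"]
               .agg(["median", _finite_mean]).reset_index()
               .rename(columns={"_finite_mean": "mean"}))
    mean_curve = summary[summary["selection"] != "random"].groupby("x")["mean"].mean()
    finite = mean_curve[np.isfinite(mean_curve)]
    slope = (linregress(finite.index.to_numpy(float), finite.to_numpy()).slope
             if len(finite) >= 2 else np.nan)
    return ScalingCurve(abscissa=grid, table=table, zscores=pd.DataFrame(zrows),
                        summary=summary, slope=float(slope))


def pair_energy_correlates(ec, fc, config: ExperimentConfig,
                           pe=None) -> pd.DataFrame:
    """Spearman correlations of log10 pairwise energy with direct coupling
    (split by sign), propagator coupling (split by sign), shortest-path
    length, and functional connectivity."""
    if pe is None:
        pe = pairwise_energies(ec)
    E = pe.E
    n = E.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(E) & off
    logE = np.where(finite, np.log10(np.where(finite, E, 1.0)), np.nan)

    A_d = ec.A.T          # direct coupling driver->target: A[j, i] at (i, j)
    P = propagator_coupling(ec, config.T).T
    L = shortest_paths(ec)
    F = fc.F

    def corr(mask: np.ndarray, other: np.ndarray) -> float:
        m = mask & finite & np.isfinite(other)
        if m.sum() < 10:
            log.warning("fewer than 10 pairs in stratum; correlation is NaN")
            return np.nan
        return float(spearmanr(logE[m], other[m]).statistic)

    rows = [
        ("direct_positive", corr(A_d > 0, A_d)),
        ("direct_negative", corr(A_d < 0, A_d)),
        ("propagator_positive", corr(P > 0, P)),
        ("propagator_negative", corr(P < 0, P)),
        ("path_length", corr(np.isfinite(L), L)),
        ("fc", corr(np.ones_like(finite), F)),
    ]
    return pd.DataFrame(rows, columns=["predictor", "spearman_r"])


def cohort_pair_energy_correlates(cohort: Cohort,
                                  config: ExperimentConfig) -> pd.DataFrame:
    frames = []
    for s, ec in enumerate(cohort):
        fc = stationary_fc(ec, config.sigma2)
        df = pair_energy_correlates(ec, fc, config)
        df["subject"] = s
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def hub_analysis(cohort: Cohort, config: ExperimentConfig | None = None,
                 pes=None) -> dict[str, pd.DataFrame]:
    """Energy-centrality vs strength correlations, across-subject coefficient
    of variation, per-node rank statistics and coordinate gradients."""
    if len(cohort) < 2:
        raise ParameterError("hub analysis needs at least two subjects")
    config = config or ExperimentConfig()
    if pes is None:
        pes = [pairwise_energies(ec) for ec in cohort]
    n = cohort.n
    per_subject = []
    Ed = np.empty((len(cohort), n))
    Et = np.empty((len(cohort), n))
    Sin = np.empty((len(cohort), n))
    Sout = np.empty((len(cohort), n))
    Fst = np.empty((len(cohort), n))
    for s, ec in enumerate(cohort):
        from .centrality import energy_centralities, fc_strength, strength_centralities
        ed, et = energy_centralities(pes[s])
        st = strength_centralities(ec)
        fs = fc_strength(stationary_fc(ec, config.sigma2))
        Ed[s], Et[s] = ed, et
        Sin[s], Sout[s] = st["in_strength"], st["out_strength"]
        Fst[s] = fs

        def sp(x, y):
            m = np.isfinite(x) & np.isfinite(y)
            return float(spearmanr(x[m], y[m]).statistic) if m.sum() > 2 else np.nan

        per_subject.append({
            "subject": s,
            "Ed_vs_out_strength": sp(np.log10(ed), Sout[s]),
            "Ed_vs_in_strength": sp(np.log10(ed), Sin[s]),
            "Ed_vs_fc_strength": sp(np.log10(ed), fs),
            "Et_vs_in_strength": sp(np.log10(et), Sin[s]),
            "Et_vs_out_strength": sp(np.log10(et), Sout[s]),
            "Et_vs_fc_strength": sp(np.log10(et), fs),
        })

    def cv(M: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.std(M, axis=0, ddof=1) / np.mean(M, axis=0)

    cv_table = pd.DataFrame({
        "node_id": np.arange(n),
        "cv_driver_energy": cv(np.log10(Ed)),
        "cv_target_energy": cv(np.log10(Et)),
        "cv_out_strength": cv(Sout),
        "cv_in_strength": cv(Sin),
    })
    from scipy.stats import rankdata
    rank_d = np.vstack([rankdata(row) for row in Ed])
    rank_t = np.vstack([rankdata(row) for row in Et])
    ranks = pd.DataFrame({
        "node_id": np.arange(n),
        "mean_rank_driver": rank_d.mean(axis=0),
        "sd_rank_driver": rank_d.std(axis=0, ddof=1),
        "mean_rank_target": rank_t.mean(axis=0),
        "sd_rank_target": rank_t.std(axis=0, ddof=1),
    })
    coords = cohort.nodes.coords
    mean_logEt = np.log10(Et).mean(axis=0)
    finite = np.isfinite(mean_logEt)
    grad = pd.DataFrame([{
        "corr_Et_y": float(np.corrcoef(mean_logEt[finite], coords[finite, 1])[0, 1]),
        "corr_Et_z": float(np.corrcoef(mean_logEt[finite], coords[finite, 2])[0, 1]),
    }])
    return {"correlations": pd.DataFrame(per_subject), "cv": cv_table,
            "ranks": ranks, "gradients": grad}


def rsn_control_analysis(cohort: Cohort, config: ExperimentConfig,
                         n_d: int = 10, include_fc: bool = True) -> pd.DataFrame:
    """Per-RSN optimal-centrality control table: individual vs aggregated
    ranking energies, their gap (as log10 difference and fold factor),
    per-node-normalized energy, and an FC-based variant."""
    pes, _ = _subject_caches(cohort, config.candidates, config, need_pe=True)
    fcs = [stationary_fc(ec, config.sigma2) for ec in cohort]
    fc_candidates = ("fc_strength", "pagerank")
    rows = []
    for rsn, n_t in sorted(cohort.nodes.rsn_sizes().items()):
        targets = TargetSet(indices=tuple(cohort.nodes.indices_of(rsn)))
        eligible = np.setdiff1d(np.arange(cohort.n), targets.indices)
        if eligible.size < n_d:
            raise ParameterError(f"RSN {rsn}: not enough remote driver candidates")
        best, results = optimal_centrality(cohort, targets, config.candidates,
                                           n_d=n_d, pes=pes)
        indiv = results[best]
        rankings = subject_rankings(cohort, best, eligible=eligible, pes=pes)
        agg = aggregate_ranks(rankings)
        agg_result = evaluate_selection(cohort, [agg] * len(cohort), n_d,
                                        targets, name=best + "_agg")
        delta = agg_result.mean_log10_energy - indiv.mean_log10_energy
        row = {
            "region": rsn, "centrality": best, "n_t": n_t, "n_d": n_d,
            "mean_log10_energy": indiv.mean_log10_energy,
            "mean_log10_energy_agg": agg_result.mean_log10_energy,
            "delta": delta,
            "fold": fold_change(delta),
            "mean_log10_energy_per_node": indiv.mean_log10_energy / n_t,
        }
        if include_fc:
            fc_best, fc_results = optimal_centrality(
                cohort, targets, fc_candidates, n_d=n_d, fcs=fcs)
            fc_indiv = fc_results[fc_best]
            fc_rankings = subject_rankings(cohort, fc_best, eligible=eligible,
                                           fcs=fcs)
            fc_agg = evaluate_selection(cohort, [aggregate_ranks(fc_rankings)] * len(cohort),
                                        n_d, targets, name=fc_best + "_agg")
            row.update({
                "fc_centrality": fc_best,
                "delta_fc": fc_agg.mean_log10_energy - fc_indiv.mean_log10_energy,
                "delta_indiv_fc_vs_ec": fc_indiv.mean_log10_energy - indiv.mean_log10_energy,
                "delta_agg_fc_vs_ec": fc_agg.mean_log10_energy - agg_result.mean_log10_energy,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def rsn_enrichment_analysis(cohort: Cohort, config: ExperimentConfig,
                            n_d: int = 10) -> dict[str, pd.DataFrame]:
    """Driver-RSN x target-RSN matrices of optimal-driver counts, with
    Fisher-exact enrichment markers over the off-diagonal RSN pairs."""
    pes, _ = _subject_caches(cohort, config.candidates, config, need_pe=True)
    node_rsn = cohort.nodes.rsn
    labels = sorted(cohort.nodes.rsn_sizes())
    counts_ind = pd.DataFrame(0.0, index=labels, columns=labels)
    counts_agg = pd.DataFrame(0.0, index=labels, columns=labels)
    enrich_rows = []
    for target_rsn in labels:
        targets = TargetSet(indices=tuple(cohort.nodes.indices_of(target_rsn)))
        eligible = np.setdiff1d(np.arange(cohort.n), targets.indices)
        best, _ = optimal_centrality(cohort, targets, config.candidates,
                                     n_d=n_d, pes=pes)
        rankings = subject_rankings(cohort, best, eligible=eligible, pes=pes)
        optimal_sets = [set(r.top(config.k)) for r in rankings]
        agg_top = set(aggregate_ranks(rankings).top(config.k))
        for driver_rsn in labels:
            in_rsn = set(np.flatnonzero(node_rsn == driver_rsn).tolist())
            counts_ind.loc[target_rsn, driver_rsn] = float(
                np.mean([len(O & in_rsn) for O in optimal_sets]))
            counts_agg.loc[target_rsn, driver_rsn] = float(len(agg_top & in_rsn))
            if driver_rsn != target_rsn:
                enrich_rows.append(enrichment_test(optimal_sets, node_rsn,
                                                   driver_rsn, target_rsn))
    marked = mark_enrichment(enrich_rows)
    return {"counts_individual": counts_ind, "counts_aggregated": counts_agg,
            "enrichment": enrichment_table(marked)}


def sensitivity_analysis(cohort: Cohort, config: ExperimentConfig,
                         centralities: tuple[str, ...] = ("out_strength", "pq"),
                         ) -> pd.DataFrame:
    """Mean top-k ranking overlap between perturbed and unperturbed matrices
    as a function of the relative noise level f."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for s, ec in enumerate(cohort):
        base_rankings = {}
        for name in centralities:
            scores = compute_centrality(ec, name)
            base_rankings[name] = rank_nodes(scores, CENTRALITY_DIRECTIONS[name])
        for f in config.f_grid:
            overlaps = {name: [] for name in centralities}
            for _ in range(config.n_sensitivity_reps):
                pec = perturb_connectome(ec, f, seed=rng)
                for name in centralities:
                    scores = compute_centrality(pec, name)
                    r = rank_nodes(scores, CENTRALITY_DIRECTIONS[name])
                    overlaps[name].append(
                        top_k_overlap(base_rankings[name], r, config.k))
            for name in centralities:
                rows.append({"subject": s, "f": f, "centrality": name,
                             "mean_overlap": float(np.mean(overlaps[name]))})
    return pd.DataFrame(rows)


def accessibility_analysis(cohort: Cohort, config: ExperimentConfig,
                           beta: AccessibilityVector | None = None) -> ScalingCurve:
    """Driver-count scaling with accessibility-attenuated inputs; the
    beta-aware pq centrality joins the candidate list."""
    if beta is None:
        beta = sample_accessibility(cohort.n, 0.01, 1.0, seed=config.seed)
    return scaling_vs_drivers(cohort, config, accessibility=beta)


# ---------------------------------------------------------------------------
# orchestration


def run_all(cohort: Cohort, config: ExperimentConfig,
            out_dir: str | Path) -> Path:
    """Execute every analysis and write a report directory of TSV tables plus
    a JSON metadata sidecar; reproducible given the config seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    failures: dict[str, str] = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # keep the partial report
            log.error("stage %s failed: %s", name, exc)
            failures[name] = str(exc)
            return
        if isinstance(result, dict):
            for sub, df in result.items():
                tables[f"{name}_{sub}"] = df
        elif isinstance(result, ScalingCurve):
            tables[f"{name}_table"] = result.table
            tables[f"{name}_summary"] = result.summary
            tables[f"{name}_zscores"] = result.zscores
        else:
            tables[name] = result

    stage("scaling_vs_drivers", lambda: scaling_vs_drivers(cohort, config))
    stage("scaling_vs_targets", lambda: scaling_vs_targets(cohort, config))
    stage("pair_energy_correlates",
          lambda: cohort_pair_energy_correlates(cohort, config))
    stage("hub_analysis", lambda: hub_analysis(cohort, config))
    stage("rsn_control", lambda: rsn_control_analysis(cohort, config))
    stage("rsn_enrichment", lambda: rsn_enrichment_analysis(cohort, config))
    stage("sensitivity", lambda: sensitivity_analysis(cohort, config))
    stage("accessibility", lambda: accessibility_analysis(cohort, config))

    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t",
                  index=not isinstance(df.index, pd.RangeIndex))

    meta = {
        "config": dataclasses.asdict(config),
        "generator_config": (cohort.config.to_dict()
                             if cohort.config is not None else None),
        "n_subjects": len(cohort),
        "n_nodes": cohort.n,
        "tables": sorted(tables),
        "failures": failures,
        "versions": {"netctrl": __version__,
                     "numpy": np.__version__,
                     "pandas": pd.__version__,
                     "python": platform.python_version()},
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    if failures:
        raise RuntimeError(f"stages failed: {sorted(failures)} (partial report in {out})")
    return out


def cohort_from_source(source: str | Path | GeneratorConfig) -> Cohort:
    """Load a cohort directory or generate one from a config."""
    if isinstance(source, GeneratorConfig):
        return generate_cohort(source)
    from .io import read_cohort
    return read_cohort(source)
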