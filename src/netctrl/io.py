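"""Plain-text persistence for cohorts, matrices and analysis tables.

A cohort directory holds ``nodes.tsv`` (node metadata), one
``<subject_id>.ec.tsv`` per subject (dense tab-separated matrix whose first
row and column carry node ids; row i, column j is the influence of j on i),
and optionally ``generator_config.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (Cohort, EffectiveConnectome, GeneratorConfig,
                         NodeTable)
from .errors import ParameterError


def write_matrix_tsv(path: Path, M: np.ndarray, node_ids=None) -> None:
    """Dense matrix with node-id header row and index column."""
    n = M.shape[0]
    ids = np.arange(n) if node_ids is None else np.asarray(node_ids)
    df = pd.DataFrame(M, index=ids, columns=ids if M.shape[1] == n else None)
    df.to_csv(path, sep="\t", index_label="node_id")


def read_matrix_tsv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float)


def write_nodes_tsv(path: Path, nodes: NodeTable) -> None:
    nodes.frame.to_csv(path, sep="\t", index=False)


def read_nodes_tsv(path: Path) -> NodeTable:
    if not Path(path).exists():
        raise ParameterError(f"missing node metadata file: {path}")
    return NodeTable(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_nodes_tsv(directory / "nodes.tsv", cohort.nodes)
    for subject in cohort:
        write_matrix_tsv(directory / f"{subject.subject_id}.ec.tsv", subject.A)
    if cohort.config is not None:
        with open(directory / "generator_config.json", "w") as fh:
            json.dump(cohort.config.to_dict(), fh, indent=2)
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    nodes = read_nodes_tsv(directory / "nodes.tsv")
    config = None
    cfg_path = directory / "generator_config.json"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = GeneratorConfig(**json.load(fh))
    subjects = []
    paths = sorted(directory.glob("*.ec.tsv"))
    if not paths:
        raise ParameterError(f"no .ec.tsv subject files in {directory}")
    tr = config.tr_seconds if config is not None else 1.4
    for p in paths:
        A = read_matrix_tsv(p)
        subjects.append(EffectiveConnectome(
            A=A, nodes=nodes, subject_id=p.name.removesuffix(".ec.tsv"),
            tr_seconds=tr))
    return Cohort(subjects=tuple(subjects), nodes=nodes, config=config)


def write_control_input_csv(path: Path, control) -> None:
    cols = {"t": control.time_grid}
    for k in range(control.u.shape[1]):
        cols[f"u_{k + 1}"] = control.u[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)
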