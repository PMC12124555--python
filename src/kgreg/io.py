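"""File input/output and run configuration.

Formats are deliberately plain: graphs as edge-list CSV (``source, target,
weight``) or symmetric Matrix Market sparse adjacency; features ``X`` and
observations ``Y`` as labelled CSV (rows = feature names / node ids, columns
= time labels); outputs as labelled CSV with fixed 12-significant-digit
formatting so runs are byte-reproducible. Node identifiers are mapped to
0-based contiguous indices and the mapping is persisted next to the outputs.

Time labels are treated as opaque ordered strings; the AR(1) noise model
assumes consecutive columns are consecutive, regularly spaced time steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .graphs import Graph
from .kgr import SelectionPattern

__all__ = [
    "RunConfig",
    "read_graph",
    "read_graph_csv",
    "read_graph_mtx",
    "load_inputs",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_node_mapping",
]

FLOAT_FORMAT = "%.12g"


def read_graph_csv(path: str | Path, normalized: bool = False):
    """Read an undirected edge-list CSV with columns source, target, weight.

    Returns ``(graph, node_labels)`` where ``node_labels[i]`` is the original
    identifier of 0-based node ``i`` (sorted label order). Listing the same
    undirected edge twice is an error.
    """
    df = pd.read_csv(path, dtype={0: str, 1: str})
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["source", "target"]:
        raise ValueError("edge list must have columns: source, target[, weight]")
    weights = df.iloc[:, 2].astype(float) if df.shape[1] >= 3 else pd.Series(1.0, index=df.index)
    labels = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    A = np.zeros((n, n))
    seen = set()
    for (u, v), w in zip(df.iloc[:, :2].itertuples(index=False), weights):
        key = (index[u], index[v]) if index[u] <= index[v] else (index[v], index[u])
        if key[0] == key[1]:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        if key in seen:
            raise ValueError(f"duplicate undirected edge {u!r} -- {v!r}")
        seen.add(key)
        A[key[0], key[1]] = A[key[1], key[0]] = w
    return Graph(A, normalized=normalized), labels


def read_graph_mtx(path: str | Path, normalized: bool = False):
    """Read a symmetric sparse adjacency in Matrix Market format."""
    A = scipy.io.mmread(str(path))
    if scipy.sparse.issparse(A):
        A = A.toarray()
    labels = [str(i) for i in range(A.shape[0])]
    return Graph(np.asarray(A, dtype=float), normalized=normalized), labels


def read_graph(path: str | Path, normalized: bool = False):
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        return read_graph_mtx(path, normalized=normalized)
    return read_graph_csv(path, normalized=normalized)


def write_matrix_csv(
    matrix: np.ndarray,
    path: str | Path,
    row_labels=None,
    col_labels=None,
) -> None:
    """Write a labelled matrix CSV with fixed 12-significant-digit floats."""
    df = pd.DataFrame(matrix, index=row_labels, columns=col_labels)
    df.to_csv(path, float_format=FLOAT_FORMAT, index_label="id")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0).astype(float)


def write_node_mapping(labels, path: str | Path) -> None:
    pd.DataFrame({"index": range(len(labels)), "label": labels}).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated configuration for a fitting run (YAML on disk)."""

    graph_path: str
    x_path: str
    y_path: str
    output_dir: str = "."
    gamma: float = 1.0
    beta: float = 1.0
    sigma: float = 1.0
    alpha: float = 0.1
    filter_family: str = "exponential"
    normalized_laplacian: bool = False
    gls: bool = True
    uncertainty: bool = False
    tol_inner: float = 1e-8
    tol_outer: float = 1e-6
    max_iter_inner: int = 100
    max_iter_outer: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("gamma", "beta", "sigma", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("graph_path", "x_path", "y_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def load_inputs(config: RunConfig):
    """Load a consistent problem instance from the configured files.

    Returns ``(graph, node_labels, X, Y, selection, time_labels)``. The
    selection pattern is inferred from the intersection of Y's row labels
    with the graph's node labels and of Y's column labels with X's time axis.
    """
    graph, labels = read_graph(config.graph_path, normalized=config.normalized_laplacian)
    label_index = {lab: i for i, lab in enumerate(labels)}
    X_df = read_matrix_csv(config.x_path)
    Y_df = read_matrix_csv(config.y_path)
    if Y_df.index.astype(str).duplicated().any() or X_df.columns.duplicated().any():
        raise ValueError("duplicate labels in input files")

    time_labels = [str(c) for c in X_df.columns]
    y_times = [str(c) for c in Y_df.columns]
    missing_t = [t for t in y_times if t not in time_labels]
    if missing_t:
        raise ValueError(f"Y has time columns not present in X: {missing_t}")
    y_nodes = [str(r) for r in Y_df.index]
    missing_n = [r for r in y_nodes if r not in label_index]
    if missing_n:
        raise ValueError(f"Y has node labels not present in the graph: {missing_n}")

    node_idx = np.array([label_index[r] for r in y_nodes])
    time_pos = {t: j for j, t in enumerate(time_labels)}
    time_idx = np.array([time_pos[t] for t in y_times])
    order_n = np.argsort(node_idx)
    order_t = np.argsort(time_idx)
    Y = Y_df.to_numpy()[np.ix_(order_n, order_t)]
    selection = SelectionPattern(
        node_idx[order_n], time_idx[order_t],
        n_total=graph.n_nodes, t_total=len(time_labels),
    )
    X = X_df.to_numpy()
    return graph, labels, X, Y, selection, time_labels
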