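"""Patient-similarity population graphs from tabular cohorts.

Each patient is a node carrying the standardized vector of selected
clinical features; two patients are connected when the cosine
similarity of their feature vectors meets a hard threshold (default
>= 0.95, inclusive).  Standardization (z-scoring) is fit on the
training cohort only and applied unchanged to the test cohort, and
train/test graphs are built separately, so no information leaks from
the test patients into graph construction or scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .synthetic_cohort import ID_COLUMN, LABEL_COLUMN


class GraphBuildError(ValueError):
    """Raised for invalid graph-construction inputs."""


@dataclass
class ScalerParams:
    """Per-feature centring/scaling constants (population sd, ddof=0)."""

    feature_names: tuple
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.size:
            raise GraphBuildError(
                f"scaler fitted on {self.mean.size} features, got {X.shape[1]}")
        return (X - self.mean) / self.sd


@dataclass
class PatientGraph:
    """A per-cohort population graph.

    node_ids : patient identifiers, in row order
    X        : standardized feature matrix, n x d
    Y        : one-hot label matrix, n x 2 (column 1 = metastasis)
    edges    : unordered node-index pairs (i, j), i < j
    A        : symmetric 0/1 adjacency with zero diagonal
    """

    node_ids: tuple
    X: np.ndarray
    Y: np.ndarray
    edges: list
    A: np.ndarray
    threshold: float
    feature_names: tuple = ()

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def labels(self) -> np.ndarray:
        return self.Y[:, 1].astype(int)


def fit_scaler(X, feature_names=None) -> ScalerParams:
    """Fit per-column mean/sd (denominator n) on a training matrix.

    Zero-variance columns are rejected by name: they carry no contrast
    and would make both scaling and cosine similarity ill-defined.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise GraphBuildError("scaler needs a 2-D matrix with at least 2 rows")
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(X.shape[1]))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = [feature_names[j] for j in zero]
        raise GraphBuildError(f"zero-variance feature(s): {names}")
    return ScalerParams(tuple(feature_names), mean, sd)


def cosine_similarity_matrix(X) -> np.ndarray:
    """Pairwise cosine similarity between rows; symmetric, unit diagonal."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise GraphBuildError(f"zero-norm row(s) {zero.tolist()}: cosine undefined")
    S = _sk_cosine(X)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def build_edges(S, tau: float):
    """Threshold a similarity matrix into an edge list and 0/1 adjacency.

    {i, j} is an edge iff i != j and S[i, j] >= tau (ties at the
    threshold included).  Isolated nodes are permitted.
    """
    S = np.asarray(S, dtype=float)
    if not -1.0 < tau <= 1.0:
        raise GraphBuildError(f"threshold must lie in (-1, 1], got {tau}")
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise GraphBuildError("similarity matrix must be square and symmetric")
    n = S.shape[0]
    A = (S >= tau).astype(np.int8)
    np.fill_diagonal(A, 0)
    iu, ju = np.nonzero(np.triu(A, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    return edges, A.astype(np.float64)


def assemble_graph(cohort: pd.DataFrame, selected, scaler: ScalerParams,
                   tau: float = 0.95) -> PatientGraph:
    """Build the population graph of one cohort.

    `selected` is the candidate-factor list (column names); `scaler`
    must have been fitted on the training cohort's values of the same
    columns, in the same order.
    """
    selected = list(selected)
    missing = [c for c in selected if c not in cohort.columns]
    if missing:
        raise GraphBuildError(f"selected features absent from cohort: {missing}")
    if tuple(selected) != scaler.feature_names:
        raise GraphBuildError(
            f"scaler was fitted on {scaler.feature_names}, asked for {tuple(selected)}")
    X = scaler.transform(cohort[selected].to_numpy(dtype=float))
    labels = cohort[LABEL_COLUMN].to_numpy(dtype=int)
    Y = np.zeros((len(cohort), 2))
    Y[np.arange(len(cohort)), labels] = 1.0
    if len(cohort) > 1:
        S = cosine_similarity_matrix(X)
        edges, A = build_edges(S, tau)
    else:
        edges, A = [], np.zeros((len(cohort), len(cohort)))
    return PatientGraph(
        node_ids=tuple(cohort[ID_COLUMN].tolist()),
        X=X, Y=Y, edges=edges, A=A, threshold=tau,
        feature_names=tuple(selected),
    )


def to_networkx(graph: PatientGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges)
    return g


def graph_summary(graph: PatientGraph) -> dict:
    """Structural diagnostics: sizes, density, components, degrees."""
    g = to_networkx(graph)
    n, m = graph.n_nodes, len(graph.edges)
    degrees = np.asarray([d for _, d in g.degree()], dtype=float) if n else np.array([])
    return {
        "n_nodes": n,
        "n_edges": m,
        "density": float(2 * m / (n * (n - 1))) if n > 1 else 0.0,
        "n_components": nx.number_connected_components(g) if n else 0,
        "n_isolated": int((degrees == 0).sum()),
        "degree_quantiles": {
            q: float(np.quantile(degrees, q)) for q in (0.0, 0.25, 0.5, 0.75, 1.0)
        } if n else {},
    }


# ---------------------------------------------------------------------------
# on-disk interchange

def export_edge_list(graph: PatientGraph, S, path) -> None:
    """Write edges as TSV (source_id, target_id, similarity)."""
    S = np.asarray(S, dtype=float)
    rows = [(graph.node_ids[i], graph.node_ids[j], S[i, j]) for i, j in graph.edges]
    pd.DataFrame(rows, columns=["source_id", "target_id", "similarity"]).to_csv(
        path, sep="\t", index=False)


def import_edge_list(path, node_ids):
    """Read an edge TSV back into (edges, A) against a fixed node order."""
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    index = {pid: i for i, pid in enumerate(node_ids)}
    n = len(node_ids)
    A = np.zeros((n, n))
    edges = []
    for src, dst in zip(df["source_id"], df["target_id"]):
        i, j = index[src], index[dst]
        edges.append((min(i, j), max(i, j)))
        A[i, j] = A[j, i] = 1.0
    return sorted(edges), A


def export_node_attributes(graph: PatientGraph, path) -> None:
    """Write per-node CSV (id, label, degree)."""
    deg = graph.A.sum(axis=1).astype(int)
    pd.DataFrame({
        "id": graph.node_ids,
        "label": graph.labels,
        "degree": deg,
    }).to_csv(path, index=False)


def export_graphml(graph: PatientGraph, path) -> None:
    g = to_networkx(graph)
    labels = graph.labels
    for i in g.nodes:
        g.nodes[i]["patient_id"] = graph.node_ids[i]
        g.nodes[i]["label"] = int(labels[i])
    nx.write_graphml(g, path)
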