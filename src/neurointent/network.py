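"""Complex brain networks from inter-channel correlations and nodal metrics.

Channels are nodes; edge weights are Fisher-Z-transformed Pearson
correlations of the 0-3.5 s observation window.  A binary graph is derived
by proportional thresholding of |Z| at a configured edge density, and five
nodal metrics are computed per channel: degree, clustering coefficient,
betweenness centrality, eigenvector centrality, and local efficiency.
Per-trial networks feed the classifier; grand-averaged (per-condition)
networks serve visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .preprocessing import EpochSet

METRICS = ("degree", "clustering", "betweenness", "eigenvector", "local_efficiency")

R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped at 1 - 1e-7 so perfect correlations stay finite."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP))


@dataclass
class ConnectivityNetwork:
    """Symmetric Fisher-Z weight matrix plus its thresholded binary graph."""

    weights: np.ndarray  # (n, n) signed Fisher Z, zero diagonal
    binary: np.ndarray  # (n, n) bool adjacency
    density: float
    node_ids: list[str]
    modality: str = ""

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def proportional_threshold(weights: np.ndarray, density: float) -> np.ndarray:
    """Binary adjacency keeping the top ``density`` fraction of |weight| edges.

    Ties at the cut are broken by a stable sort on (|weight| descending,
    node-pair lexicographic ascending).
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mag = np.abs(weights[iu, ju])
    n_keep = int(round(density * len(mag)))
    adj = np.zeros((n, n), dtype=bool)
    if n_keep <= 0:
        return adj
    order = np.lexsort((ju, iu, -mag))
    sel = order[:n_keep]
    adj[iu[sel], ju[sel]] = True
    adj |= adj.T
    return adj


def connectivity(
    window: np.ndarray,
    density: float = 0.3,
    node_ids: list[str] | None = None,
    modality: str = "",
) -> ConnectivityNetwork:
    """Pairwise Pearson -> Fisher Z -> proportional binary threshold.

    ``window`` is (channels, time); constant channels get zero edges with a
    warning.
    """
    window = np.asarray(window, dtype=float)
    n, t = window.shape
    if t < 3:
        raise ValueError("connectivity window needs at least 3 samples")
    sd = window.std(axis=1)
    const = sd <= 1e-13 * np.maximum(1.0, np.abs(window).max(axis=1))
    if const.any():
        warnings.warn(
            f"constant channel(s) {np.where(const)[0].tolist()}: edges set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(window)
    r[const, :] = 0.0
    r[:, const] = 0.0
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    binary = proportional_threshold(z, density)
    ids = node_ids or [f"n{i}" for i in range(n)]
    return ConnectivityNetwork(z, binary, density, list(ids), modality)


# --------------------------------------------------------------------------
# Nodal metrics on a boolean adjacency matrix


def degree(adj: np.ndarray) -> np.ndarray:
    return np.asarray(adj, dtype=int).sum(axis=1).astype(float)


def clustering_coefficient(adj: np.ndarray) -> np.ndarray:
    """2 * triangles(i) / (k_i * (k_i - 1)); 0 where degree < 2."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1) / 2.0
    out = np.zeros(len(k))
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def _graph(adj: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(adj, dtype=int))

def betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness centrality; unreachable pairs contribute 0."""
    g = _graph(adj)
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(len(adj))])


def eigenvector_centrality(adj: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the largest connected component's adjacency.

    Nonnegative entries, unit Euclidean norm over the component; nodes
    outside the component (and every node of an edgeless graph) get 0.
    Components are tied-broken toward the one containing the smallest node
    index.
    """
    a = np.asarray(adj, dtype=float)
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    g = _graph(a)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    out = np.zeros(n)
    if not comps or len(comps[0]) < 2:
        return out
    nodes = sorted(comps[0])
    sub = a[np.ix_(nodes, nodes)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of a connected graph is strictly positive
    v /= np.linalg.norm(v)
    out[nodes] = v
    return out


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph.

    Global efficiency = mean over ordered node pairs of 1/shortest-path
    length (0 for unreachable pairs); nodes of degree < 2 get 0.
    """
    g = _graph(adj)
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = list(g[i])
        if len(nbrs) < 2:
            continue
        out[i] = nx.global_efficiency(g.subgraph(nbrs))
    return out


_METRIC_FUNCS = {
    "degree": degree,
    "clustering": clustering_coefficient,
    "betweenness": betweenness,
    "eigenvector": eigenvector_centrality,
    "local_efficiency": local_efficiency,
}


def nodal_features(net: ConnectivityNetwork) -> np.ndarray:
    """(n_channels, 5) metric matrix in the documented column order."""
    return np.stack([_METRIC_FUNCS[m](net.binary) for m in METRICS], axis=1)


@dataclass
class NodalFeatureTable:
    """Trials x (channels * 5 metrics) feature matrix with provenance."""

    values: np.ndarray
    columns: list[str]  # "<modality>:<channel>:<metric>"
    labels: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.labels), len(self.columns)):
            raise ValueError("feature table shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def _column_names(node_ids: list[str], modality: str) -> list[str]:
    # channel-major order: all five metrics of channel 0, then channel 1, ...
    return [f"{modality}:{ch}:{m}" for ch in node_ids for m in METRICS]


def feature_table(
    epochs: EpochSet,
    window_s: tuple[float, float] = (0.0, 3.5),
    density: float = 0.3,
) -> NodalFeatureTable:
    """Per-trial networks on the observation window -> nodal feature table."""
    mask = epochs.time_mask(*window_s)
    if mask.sum() < 3:
        raise ValueError(f"window {window_s} has fewer than 3 samples")
    ids = epochs.channel_names or [f"ch{i + 1}" for i in range(epochs.n_channels)]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-channel warnings per trial
        for trial in range(epochs.n_trials):
            net = connectivity(
                epochs.data[trial][:, mask], density, ids, epochs.modality
            )
            rows.append(nodal_features(net).reshape(-1))
    return NodalFeatureTable(
        values=np.asarray(rows),
        columns=_column_names(ids, epochs.modality),
        labels=epochs.labels.copy(),
        modality=epochs.modality,
    )


def grand_average_networks(
    epochs: EpochSet,
    window_s: tuple[float, float] = (0.0, 3.5),
    density: float = 0.3,
) -> dict[str, ConnectivityNetwork]:
    """Condition-wise networks of the trial-averaged observation window."""
    mask = epochs.time_mask(*window_s)
    ids = epochs.channel_names or [f"ch{i + 1}" for i in range(epochs.n_channels)]
    out = {}
    for cond in epochs.conditions():
        avg = epochs.data[epochs.labels == cond].mean(axis=0)
        out[cond] = connectivity(avg[:, mask], density, ids, epochs.modality)
    return out


class NodalFeatureExtractor:
    """sklearn-style transformer: (trials, channels, time) -> nodal features.

    Stateless; ``fit`` records channel count only.  Provided so the network
    stage composes with sklearn pipelines.
    """

    def __init__(self, density: float = 0.3, modality: str = ""):
        self.density = density
        self.modality = modality

    def get_params(self, deep: bool = True) -> dict:
        return {"density": self.density, "modality": self.modality}

    def set_params(self, **params) -> "NodalFeatureExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "NodalFeatureExtractor":
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expects trials x channels x time")
        self.n_channels_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for trial in range(X.shape[0]):
                net = connectivity(X[trial], self.density, modality=self.modality)
                rows.append(nodal_features(net).reshape(-1))
        return np.asarray(rows)

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
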