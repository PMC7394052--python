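"""Multiplex muscle networks: construction from synergies and coherence
components, minimally-connected thresholding, Louvain community structure,
and weighted graph metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .muscles import MUSCLES, N_MUSCLES

__all__ = [
    "MultiplexNetwork",
    "Partition",
    "LayerMetrics",
    "synergy_layers",
    "coherence_layers",
    "minimally_connect",
    "communities",
    "layer_metrics",
    "compare_partitions",
]


@dataclass
class MultiplexNetwork:
    layers: list  # of (n, n) symmetric non-negative arrays, zero diagonal
    layer_labels: list
    node_labels: list = field(default_factory=lambda: list(MUSCLES))

    def __post_init__(self):
        checked = []
        for lab, L in zip(self.layer_labels, self.layers):
            L = np.asarray(L, dtype=float)
            if L.shape[0] != L.shape[1]:
                raise ValueError(f"layer {lab} is not square")
            if not np.allclose(L, L.T):
                raise ValueError(f"layer {lab} is not symmetric")
            if np.any(L < 0):
                raise ValueError(f"layer {lab} has negative weights")
            L = L.copy()
            np.fill_diagonal(L, 0.0)
            checked.append(L)
        self.layers = checked

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]


@dataclass
class Partition:
    membership: np.ndarray  # node -> community id
    modularity_per_layer: list
    modularity_aggregate: float = float("nan")

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.membership).size)


@dataclass
class LayerMetrics:
    global_efficiency: float
    transitivity: float
    average_strength: float


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

def synergy_layers(model, envelope_index: list | None = None, n: int = 200) -> MultiplexNetwork:
    """One layer per synergy: outer product w_j w_j^T (diagonal zeroed),
    weighted by the summed trapezoidal integral over the gait cycle of the
    synergy's condition-averaged waveforms."""
    W, A, m = model.W, model.A, model.m
    sc = A.shape[1] // n
    layers, labels = [], []
    pct = np.linspace(0.0, 100.0, n)
    for j in range(m):
        strides = A[j].reshape(sc, n)
        weight = float(sum(np.trapezoid(strides[s], pct) for s in range(sc)))
        L = np.outer(W[:, j], W[:, j]) * weight
        np.fill_diagonal(L, 0.0)
        layers.append(L)
        labels.append(f"S{j + 1}")
    return MultiplexNetwork(layers=layers, layer_labels=labels,
                            node_labels=list(MUSCLES)[: W.shape[0]])


def coherence_layers(
    components, cset, condition_order: tuple = ("2:1", "T", "1:1")
) -> MultiplexNetwork:
    """One layer per (frequency component, condition): the component's 325
    pair weights arranged into a symmetric 26 x 26 matrix, averaged over
    subjects."""
    cols = cset.columns
    conditions = [c for c in condition_order if any(col[1] == c for col in cols)]
    if not conditions:
        raise ValueError("no conditions present in the coherence set")
    layers, labels = [], []
    for comp in range(components.m):
        weights = components.A[comp]  # one weight per column of C2
        for cond in conditions:
            M = np.zeros((N_MUSCLES, N_MUSCLES))
            counts = np.zeros((N_MUSCLES, N_MUSCLES))
            for col, (subj, c, (i, j)) in enumerate(cols):
                if c != cond:
                    continue
                M[i, j] += weights[col]
                M[j, i] += weights[col]
                counts[i, j] += 1
                counts[j, i] += 1
            nz = counts > 0
            M[nz] /= counts[nz]
            layers.append(M)
            labels.append(f"F{comp + 1}|{cond}")
    return MultiplexNetwork(layers=layers, layer_labels=labels)


# --------------------------------------------------------------------------
# minimally-connected thresholding
# --------------------------------------------------------------------------

def minimally_connect(net: MultiplexNetwork) -> tuple[MultiplexNetwork, float, dict]:
    """Largest global threshold tau* keeping every node attached through at
    least one supra-threshold edge in some layer; every layer then keeps an
    equal number k of strongest edges (k = max supra-threshold count).

    Returns (thresholded network, tau*, edge-weight stats).
    """
    n = net.n_nodes
    stacked = np.stack(net.layers)  # (L, n, n)
    best_per_node = stacked.max(axis=0).max(axis=1)  # strongest incident edge
    active = best_per_node > 0
    if not np.any(active):
        raise ValueError("network has no edges")
    tau = float(best_per_node[active].min())

    k = 0
    for L in net.layers:
        iu = np.triu_indices(n, 1)
        k = max(k, int(np.sum(L[iu] >= tau)))

    new_layers, removed, preserved = [], [], []
    for lab, L in zip(net.layer_labels, net.layers):
        iu = np.triu_indices(n, 1)
        w = L[iu]
        nz = np.flatnonzero(w > 0)
        order = nz[np.argsort(-w[nz], kind="stable")]
        keep = order[:k]
        if nz.size < k:
            warnings.warn(
                f"layer {lab} has only {nz.size} nonzero edges (< k={k}); keeping all",
                stacklevel=2,
            )
            keep = nz
        mask_flat = np.zeros_like(w, dtype=bool)
        mask_flat[keep] = True
        L2 = np.zeros_like(L)
        L2[iu[0][mask_flat], iu[1][mask_flat]] = w[mask_flat]
        L2 = L2 + L2.T
        new_layers.append(L2)
        preserved.extend(w[mask_flat].tolist())
        removed.extend(w[nz[~mask_flat[nz]]].tolist())

    stats = {
        "threshold": tau,
        "edges_per_layer": k,
        "n_removed": len(removed),
        "removed_mean": float(np.mean(removed)) if removed else 0.0,
        "removed_sd": float(np.std(removed)) if removed else 0.0,
        "preserved_mean": float(np.mean(preserved)) if preserved else 0.0,
        "preserved_sd": float(np.std(preserved)) if preserved else 0.0,
    }
    out = MultiplexNetwork(
        layers=new_layers, layer_labels=list(net.layer_labels),
        node_labels=list(net.node_labels),
    )
    return out, tau, stats


# --------------------------------------------------------------------------
# communities
# --------------------------------------------------------------------------

def _graph_from_matrix(M: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(M.shape[0]))
    ii, jj = np.nonzero(np.triu(M, 1))
    G.add_weighted_edges_from((int(i), int(j), float(M[i, j])) for i, j in zip(ii, jj))
    return G


def aggregate_layers(net: MultiplexNetwork) -> np.ndarray:
    """Mean of the layers after normalizing each to unit total weight."""
    agg = np.zeros_like(net.layers[0])
    for L in net.layers:
        total = L.sum()
        if total > 0:
            agg += L / total
    return agg / len(net.layers)


def communities(net: MultiplexNetwork, seed: int = 0, n_runs: int = 10) -> Partition:
    """Louvain modularity optimization on the layer-averaged adjacency; best
    of ``n_runs`` seeded restarts; per-layer modularity evaluated post hoc."""
    if not net.layers:
        raise ValueError("empty network")
    agg = aggregate_layers(net)
    if agg.sum() == 0:
        raise ValueError("network has no edges")
    G = _graph_from_matrix(agg)
    best_q, best_comms = -np.inf, None
    for r in range(n_runs):
        comms = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        q = nx.community.modularity(G, comms, weight="weight")
        if q > best_q:
            best_q, best_comms = q, comms
    membership = np.empty(net.n_nodes, dtype=int)
    for cid, nodes in enumerate(sorted(best_comms, key=min)):
        for node in nodes:
            membership[node] = cid
    comms_sets = [set(np.flatnonzero(membership == c)) for c in np.unique(membership)]
    per_layer = []
    for L in net.layers:
        if L.sum() == 0:
            per_layer.append(float("nan"))
            continue
        per_layer.append(
            float(nx.community.modularity(_graph_from_matrix(L), comms_sets,
                                          weight="weight"))
        )
    return Partition(
        membership=membership,
        modularity_per_layer=per_layer,
        modularity_aggregate=float(best_q),
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def layer_metrics(layer: np.ndarray) -> LayerMetrics:
    """Weighted global efficiency (lengths 1/w after max-normalization),
    weighted transitivity (geometric-mean triangle weights), and average
    node strength."""
    L = np.asarray(layer, dtype=float)
    if not np.allclose(L, L.T) or np.any(L < 0):
        raise ValueError("layer must be symmetric and non-negative")
    n = L.shape[0]
    wmax = L.max()
    if wmax == 0:
        warnings.warn("all-zero layer: metrics are 0", stacklevel=2)
        return LayerMetrics(0.0, 0.0, 0.0)
    Wn = L / wmax

    lengths = np.full_like(Wn, np.inf)
    nz = Wn > 0
    lengths[nz] = 1.0 / Wn[nz]
    np.fill_diagonal(lengths, 0.0)
    D = shortest_path(lengths, method="D", directed=False)
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[iu]
    inv[~np.isfinite(inv)] = 0.0
    efficiency = float(inv.mean())

    cbrt = np.cbrt(Wn)
    closed = float(np.trace(cbrt @ cbrt @ cbrt))  # closed weighted triplets
    # open+closed triplets centered at i: sum_{j != k} sqrt(w_ij w_ik)
    row = np.sqrt(Wn).sum(axis=1)
    triplets = float(np.sum(row**2 - Wn.sum(axis=1)))
    transitivity = closed / triplets if triplets > 0 else 0.0

    strength = float(L.sum(axis=1).mean())
    return LayerMetrics(efficiency, transitivity, strength)


# --------------------------------------------------------------------------
# partition comparison
# --------------------------------------------------------------------------

def rand_index(p1: np.ndarray, p2: np.ndarray) -> float:
    """Plain Rand index by pair counting."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    agree = 0
    pairs = list(combinations(range(p1.size), 2))
    for i, j in pairs:
        same1 = p1[i] == p1[j]
        same2 = p2[i] == p2[j]
        agree += same1 == same2
    return agree / len(pairs)


def compare_partitions(
    p1: np.ndarray, p2: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Rand index, adjusted Rand index, and a label-permutation p-value."""
    from sklearn.metrics import adjusted_rand_score

    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.size != p2.size:
        raise ValueError("partitions must cover the same node set")
    if p1.size < 2:
        raise ValueError("need at least 2 nodes")
    ri = rand_index(p1, p2)
    ari = float(adjusted_rand_score(p1, p2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(p2)
        if adjusted_rand_score(p1, perm) >= ari:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    return {"rand": float(ri), "adjusted_rand": ari, "p_value": float(pval)}
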