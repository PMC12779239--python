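"""Generalized-correlation networks and allosteric shortest paths.

Residue motions are scored with the generalized correlation coefficient
r_MI = sqrt(1 - exp(-2 I / d)), where I is the mutual information between
the d = 3 dimensional displacement vectors of two nodes (default: one Ca
bead per residue), estimated with the Kraskov k-nearest-neighbour
estimator. Correlation matrices are filtered by an occupancy contact map
(heavy-atom distance within a cutoff for at least a stated fraction of
frames) and turned into a weighted graph with edge weight -log10(r_MI);
preferential allosteric pathways are minimum-total-weight Dijkstra paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree
from scipy.special import digamma

from .core import Selection, TrajectoryEnsemble
from .flexibility import superpose_stack

__all__ = [
    "CorrelationMatrix", "OccupancyContactMap", "AllostericPath",
    "ksg_mutual_information", "mi_matrix_knn", "generalized_correlation",
    "occupancy_contact_map", "build_graph", "shortest_paths", "replica_average",
    "correlation_difference", "node_displacements",
]


@dataclass
class CorrelationMatrix:
    """Symmetric generalized-correlation matrix with its MI matrix."""

    r: np.ndarray                  # r_MI in [0, 1], diagonal 1
    mi: np.ndarray                 # nats
    d: int = 3
    k: int = 6
    stride: int = 1
    node_labels: list = None


@dataclass
class OccupancyContactMap:
    contacts: np.ndarray           # boolean, symmetric, diagonal False
    cutoff: float = 0.5
    occupancy_threshold: float = 0.70
    occupancy: np.ndarray = None   # observed per-pair occupancies


@dataclass
class AllostericPath:
    source: int
    target: int
    nodes: list = None
    edge_weights: list = None
    total_weight: float = None
    reachable: bool = True


# ---------------------------------------------------------------------------
# Mutual information (Kraskov algorithm 1, Chebyshev metric)
# ---------------------------------------------------------------------------

def ksg_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 6) -> float:
    """KSG estimator of I(X;Y) in nats for continuous vector samples.

    ``x``/``y``: (n_samples, d) arrays. Chebyshev (max) norm in the joint
    and marginal spaces; marginal counts use the strictly-within rule.
    The estimate is clamped at 0.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n = x.shape[0]
    if n <= k + 1:
        raise ValueError(f"need more than k+1={k+1} samples, got {n}")
    z = np.hstack([x, y])
    tree = cKDTree(z)
    dist, _ = tree.query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strictly-less-than-eps counts in each marginal
    shrink = eps * (1.0 - 1e-10)
    tx, ty = cKDTree(x), cKDTree(y)
    nx_ = tx.query_ball_point(x, shrink, p=np.inf, return_length=True) - 1
    ny_ = ty.query_ball_point(y, shrink, p=np.inf, return_length=True) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    return float(max(mi, 0.0))


def node_displacements(traj: TrajectoryEnsemble, selection: Selection,
                       stride: int = 1, superpose: bool = True):
    """Per-replica displacement stacks for MI estimation.

    Frames are strided, globally superposed onto the ensemble mean (two
    iterations, fitting on the selection) so rigid-body motion does not
    masquerade as correlation, and centred per node. Returns a list of
    (n_frames, n_nodes, 3) arrays.

    ``superpose=False`` skips the fit; use it for ensembles that have no
    rigid-body motion by construction (synthetic Gaussian systems), where
    removing six rigid degrees of freedom from a handful of beads would
    itself induce spurious correlation.
    """
    idx = selection.indices
    out = []
    for rep in traj.replicas:
        coords = rep.coords[traj.analysis_mask(rep)][::stride]
        fitted = coords
        if superpose:
            for _ in range(2):
                mean_structure = fitted.mean(axis=0)
                fitted = superpose_stack(fitted, mean_structure, idx)
        nodes = fitted[:, idx]
        out.append(nodes - nodes.mean(axis=0))
    return out


def mi_matrix_knn(traj: TrajectoryEnsemble, selection: Selection, k: int = 6,
                  stride: int = 10, min_frames: int = 100, superpose: bool = True,
                  pairs=None):
    """Pairwise MI matrices between 3-D node displacement vectors, one per
    replica (the replica-averaging convention averages r_MI afterwards).

    ``pairs`` restricts estimation to the given node-index pairs (e.g. the
    contact map's edges, the only ones the filtered graph uses); other
    entries stay 0. The full matrix is computed when ``pairs`` is None.
    """
    stacks = node_displacements(traj, selection, stride, superpose=superpose)
    matrices = []
    for disp in stacks:
        n_frames, n_nodes, _ = disp.shape
        if n_frames < min_frames:
            raise ValueError(
                f"only {n_frames} analysis frames after stride; need >= {min_frames}")
        wanted = (pairs if pairs is not None
                  else [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)])
        mi = np.zeros((n_nodes, n_nodes))
        for i, j in wanted:
            if i == j:
                continue
            mi[i, j] = mi[j, i] = ksg_mutual_information(disp[:, i], disp[:, j], k=k)
        matrices.append(mi)
    return matrices


def generalized_correlation(mi: np.ndarray, d: int = 3, k: int = 6,
                            stride: int = 1, node_labels=None) -> CorrelationMatrix:
    """r_MI = sqrt(1 - exp(-2 I / d)) element-wise, diagonal forced to 1."""
    mi = np.asarray(mi, float)
    if np.any(mi < 0):
        raise ValueError("MI matrix must be non-negative")
    r = np.sqrt(1.0 - np.exp(-2.0 * mi / d))
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, mi=mi, d=d, k=k, stride=stride, node_labels=node_labels)


# ---------------------------------------------------------------------------
# Contact map
# ---------------------------------------------------------------------------

def occupancy_contact_map(traj: TrajectoryEnsemble, cutoff: float = 0.5,
                          occupancy: float = 0.70, heavy_only: bool = True,
                          residue_subset=None) -> OccupancyContactMap:
    """Residue pairs in contact: any heavy-atom pair within ``cutoff`` (nm,
    inclusive) for at least ``occupancy`` (inclusive) of the pooled
    analysis frames."""
    top = traj.topology
    residues = (list(residue_subset) if residue_subset is not None
                else list(range(top.n_residues)))
    res_atoms = []
    for r in residues:
        idx = np.asarray(top.residues[r].atom_indices)
        if heavy_only:
            idx = idx[top.heavy_mask[idx]]
        res_atoms.append(idx)
    n = len(residues)
    atom_idx = np.concatenate(res_atoms)
    onehot = np.zeros((len(atom_idx), n))
    start = 0
    for r, idx in enumerate(res_atoms):
        onehot[start:start + len(idx), r] = 1.0
        start += len(idx)
    single_atom = all(len(idx) == 1 for idx in res_atoms)
    hit_counts = np.zeros((n, n))
    total_frames = 0
    for rep in traj.replicas:
        coords = rep.coords[traj.analysis_mask(rep)][:, atom_idx]
        total_frames += coords.shape[0]
        if single_atom:
            diff = coords[:, :, None, :] - coords[:, None, :, :]
            within = (diff**2).sum(axis=3) <= cutoff * cutoff
            hit_counts += within.sum(axis=0)
        else:
            # frame-wise atom distance matrix reduced to residue-pair hits
            for f in range(coords.shape[0]):
                diff = coords[f, :, None, :] - coords[f, None, :, :]
                within = (diff**2).sum(axis=2) <= cutoff * cutoff
                pair_hits = onehot.T @ within @ onehot > 0
                hit_counts += pair_hits
    occ = hit_counts / max(total_frames, 1)
    contacts = occ >= occupancy - 1e-12     # inclusive boundary
    np.fill_diagonal(contacts, False)
    return OccupancyContactMap(contacts=contacts, cutoff=cutoff,
                               occupancy_threshold=occupancy, occupancy=occ)


# ---------------------------------------------------------------------------
# Graph construction and shortest paths
# ---------------------------------------------------------------------------

def build_graph(corr: CorrelationMatrix, contacts: OccupancyContactMap) -> nx.Graph:
    """Weighted graph: edges where the contact map is true, weight
    -log10(r_MI); r <= 0 (infinite weight) omits the edge; r is clipped at
    1 so weights are >= 0."""
    r = corr.r
    if r.shape != contacts.contacts.shape:
        raise ValueError(
            f"correlation matrix {r.shape} and contact map "
            f"{contacts.contacts.shape} node sets differ")
    n = r.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contacts.contacts[i, j]:
                continue
            rij = min(r[i, j], 1.0)
            if rij <= 0.0 or not np.isfinite(rij):
                continue
            g.add_edge(i, j, weight=float(-np.log10(rij)))
    return g


def shortest_paths(graph: nx.Graph, source, targets, weight_tol: float = 1e-12):
    """Minimum-total-weight Dijkstra path to each target.

    Ties are broken deterministically: among equal-weight shortest paths
    the lexicographically smallest node sequence is returned, built by
    greedily taking the smallest next node that still lies on an optimal
    path. Unreachable targets are reported with ``reachable=False``.
    """
    if source not in graph:
        raise ValueError(f"source node {source!r} not in graph")
    dist_from_source = nx.single_source_dijkstra_path_length(graph, source)
    results = []
    for target in targets:
        if target not in graph or target not in dist_from_source:
            results.append(AllostericPath(source=source, target=target, reachable=False))
            continue
        if target == source:
            results.append(AllostericPath(source=source, target=target, nodes=[source],
                                          edge_weights=[], total_weight=0.0))
            continue
        dist_to_target = nx.single_source_dijkstra_path_length(graph, target)
        total = dist_from_source[target]
        path = [source]
        node = source
        travelled = 0.0
        while node != target:
            candidates = []
            for nb in graph.neighbors(node):
                if nb in path:
                    continue
                w = graph[node][nb]["weight"]
                if nb in dist_to_target and \
                   abs(travelled + w + dist_to_target[nb] - total) <= weight_tol * max(1.0, abs(total)) + weight_tol:
                    candidates.append(nb)
            node = min(candidates)
            travelled += graph[path[-1]][node]["weight"]
            path.append(node)
        weights = [graph[a][b]["weight"] for a, b in zip(path[:-1], path[1:])]
        results.append(AllostericPath(source=source, target=target, nodes=path,
                                      edge_weights=weights, total_weight=float(sum(weights))))
    return results


# ---------------------------------------------------------------------------
# Replica averaging and system differences
# ---------------------------------------------------------------------------

def replica_average(matrices) -> CorrelationMatrix:
    """Element-wise mean of per-replica r_MI matrices."""
    mats = [m.r if isinstance(m, CorrelationMatrix) else np.asarray(m, float)
            for m in matrices]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"replica matrices have differing node sets: {shapes}")
    mean_r = np.mean(mats, axis=0)
    mis = [m.mi for m in matrices if isinstance(m, CorrelationMatrix)]
    mean_mi = np.mean(mis, axis=0) if len(mis) == len(matrices) else np.zeros_like(mean_r)
    first = matrices[0]
    meta = first if isinstance(first, CorrelationMatrix) else None
    return CorrelationMatrix(
        r=mean_r, mi=mean_mi,
        d=meta.d if meta else 3, k=meta.k if meta else 6,
        stride=meta.stride if meta else 1,
        node_labels=meta.node_labels if meta else None)


def correlation_difference(system1, system2) -> np.ndarray:
    """Per-pair difference mean(system1) - mean(system2) of replica-averaged
    r_MI matrices."""
    m1 = replica_average(system1 if isinstance(system1, (list, tuple)) else [system1])
    m2 = replica_average(system2 if isinstance(system2, (list, tuple)) else [system2])
    if m1.r.shape != m2.r.shape:
        raise ValueError("systems have differing node sets")
    return m1.r - m2.r
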