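"""Polar-map graph, combinatorial Laplacian, and Graclus-style coarsening.

The 460 grid nodes form an undirected unit-weight graph: each node is
connected to its two angular neighbours on the same ring (with wrap-around)
and to the radially adjacent nodes on the neighbouring rings.  Pooling in
the graph networks relies on a multilevel coarsening hierarchy built by
greedy pair matching; unmatched nodes become singletons and are padded with
isolated "fake" nodes so that every level has exactly twice the nodes of
the next, which makes pooling a reshape-and-reduce over contiguous sibling
blocks after a one-off node permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .polarmap import N_NODES, N_RINGS, N_SECTORS, node_index


@dataclass
class Graph:
    """Undirected weighted graph with its combinatorial Laplacian."""

    adjacency: sp.csr_matrix
    laplacian: sp.csr_matrix
    lambda_max: float

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def laplacian(A: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Combinatorial Laplacian L = D - A with D = diag(row sums)."""
    A = sp.csr_matrix(A)
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    if np.any(A.diagonal() != 0):
        raise ValueError("adjacency must have zero diagonal")
    d = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(d) - A).tocsr()


def max_eigenvalue(L: sp.spmatrix) -> float:
    """Largest Laplacian eigenvalue, by dense symmetric eigensolver."""
    return float(np.linalg.eigvalsh(L.toarray())[-1])


def make_graph(A: sp.spmatrix | np.ndarray) -> Graph:
    L = laplacian(A)
    lam = max_eigenvalue(L) if L.shape[0] else 0.0
    return Graph(adjacency=sp.csr_matrix(A), laplacian=L, lambda_max=lam)


def rescale_laplacian(L: sp.spmatrix, lambda_max: float) -> sp.csr_matrix:
    """Map the spectrum of L into [-1, 1]: L~ = (2/lambda_max) L - I."""
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    n = L.shape[0]
    return ((2.0 / lambda_max) * L - sp.identity(n)).tocsr()


def build_polar_adjacency() -> Graph:
    """Unit-weight graph of the 20x23 polar grid (angular wrap, no pole link)."""
    rows, cols = [], []
    for r in range(N_RINGS):
        for s in range(N_SECTORS):
            i = node_index(r, s)
            rows.append(i)
            cols.append(node_index(r, (s + 1) % N_SECTORS))
            if r + 1 < N_RINGS:
                rows.append(i)
                cols.append(node_index(r + 1, s))
    A = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(N_NODES, N_NODES)
    )
    A = ((A + A.T) > 0).astype(float).tocsr()
    return make_graph(A)


# ---------------------------------------------------------------------------
# Coarsening
# ---------------------------------------------------------------------------


@dataclass
class GraphHierarchy:
    """Multilevel coarsening with fake-node padding and pooling permutation.

    ``levels[k]`` is the padded graph at level k (level 0 = input graph plus
    padding); ``parent[k]`` maps padded level-k nodes to padded level-(k+1)
    nodes; ``perm`` reorders the original input nodes into the padded level-0
    layout (``perm[j]`` = original index at padded slot j, -1 for fakes);
    ``fake_mask[k]`` marks padding nodes at level k.
    """

    levels: list[Graph]
    parent: list[np.ndarray]
    perm: np.ndarray
    fake_mask: list[np.ndarray]

    @property
    def n_levels(self) -> int:
        return len(self.levels) - 1

    def permute_signal(self, x: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Reorder (..., n_original) signals into the padded level-0 layout."""
        n0 = self.levels[0].n
        out = np.full(x.shape[:-1] + (n0,), fill, dtype=float)
        real = self.perm >= 0
        out[..., real] = x[..., self.perm[real]]
        return out


def _greedy_matching(A: sp.csr_matrix, rng: np.random.Generator) -> np.ndarray:
    """Pair nodes greedily by the normalized-cut score A_ij (1/d_i + 1/d_j).

    Nodes are visited in ascending-degree order (ties by index); each picks
    its best unmatched neighbour.  Returns cluster ids (coarse node per fine
    node); unmatched nodes become singleton clusters.  Deterministic for a
    given adjacency; ``rng`` reserved for optional visit-order jitter.
    """
    n = A.shape[0]
    d = np.asarray(A.sum(axis=1)).ravel()
    order = np.lexsort((np.arange(n), d))
    cluster = -np.ones(n, dtype=int)
    indptr, indices, data = A.indptr, A.indices, A.data
    nxt = 0
    for i in order:
        if cluster[i] >= 0:
            continue
        best_j, best_score = -1, -1.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            if cluster[j] >= 0 or j == i:
                continue
            w = data[ptr]
            score = w * (1.0 / max(d[i], 1e-12) + 1.0 / max(d[j], 1e-12))
            if score > best_score + 1e-15 or (
                abs(score - best_score) <= 1e-15 and (best_j == -1 or j < best_j)
            ):
                best_j, best_score = j, score
        cluster[i] = nxt
        if best_j >= 0:
            cluster[best_j] = nxt
        nxt += 1
    return cluster


def _coarse_adjacency(A: sp.csr_matrix, cluster: np.ndarray) -> sp.csr_matrix:
    """Sum edge weights between clusters; drop intra-cluster self-loops."""
    m = cluster.max() + 1 if cluster.size else 0
    P = sp.coo_matrix(
        (np.ones(len(cluster)), (cluster, np.arange(len(cluster)))),
        shape=(m, len(cluster)),
    ).tocsr()
    Ac = (P @ A @ P.T).tolil()
    Ac.setdiag(0)
    Ac = Ac.tocsr()
    Ac.eliminate_zeros()
    return Ac


def coarsen(graph: Graph, n_levels: int, seed: int = 0) -> GraphHierarchy:
    """Build an n_levels-deep coarsening hierarchy with fake-node padding."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    rng = np.random.default_rng(seed)

    adjs = [graph.adjacency.tocsr()]
    clusters: list[np.ndarray] = []
    for _ in range(n_levels):
        cl = _greedy_matching(adjs[-1], rng)
        if cl.size and cl.max() + 1 < 1:
            raise ValueError("coarsening produced an empty level")
        clusters.append(cl)
        adjs.append(_coarse_adjacency(adjs[-1], cl))

    # children lists per level (coarse node -> fine nodes), then pad binary
    # trees bottom-up so each coarse node has exactly two padded children.
    children: list[list[list[int]]] = []
    for k in range(n_levels):
        m = clusters[k].max() + 1
        ch: list[list[int]] = [[] for _ in range(m)]
        for fine, c in enumerate(clusters[k]):
            ch[c].append(fine)
        children.append(ch)

    # order of coarsest-level nodes is their natural order
    n_top = adjs[-1].shape[0]
    order_top = list(range(n_top))

    # walk down: padded order of level k nodes, -1 marks a fake slot
    padded_orders: list[list[int]] = [order_top]
    for k in range(n_levels - 1, -1, -1):
        order_fine: list[int] = []
        for c in padded_orders[0]:
            if c < 0:  # fake parent -> two fake children
                order_fine.extend([-1, -1])
            else:
                kids = sorted(children[k][c])
                if len(kids) == 1:
                    kids = kids + [-1]
                order_fine.extend(kids)
        padded_orders.insert(0, order_fine)

    levels: list[Graph] = []
    fake_masks: list[np.ndarray] = []
    parents: list[np.ndarray] = []
    pos_of: list[dict[int, int]] = []  # original node -> padded slot per level
    for k, order in enumerate(padded_orders):
        nk = len(order)
        mask = np.array([o < 0 for o in order])
        A_real = adjs[k]
        keep = [o for o in order if o >= 0]
        slot = {o: j for j, o in enumerate(order) if o >= 0}
        rowsel = np.array(keep, dtype=int)
        Ak = sp.lil_matrix((nk, nk))
        sub = A_real[rowsel][:, rowsel]
        js = np.array([slot[o] for o in keep], dtype=int)
        sub = sub.tocoo()
        Ak[js[sub.row], js[sub.col]] = sub.data
        Ak = Ak.tocsr()
        levels.append(make_graph(Ak))
        fake_masks.append(mask)
        pos_of.append(slot)

    for k in range(n_levels):
        order = padded_orders[k]
        par = np.empty(len(order), dtype=int)
        for j in range(len(order)):
            par[j] = j // 2
        parents.append(par)

    perm = np.array(padded_orders[0], dtype=int)
    return GraphHierarchy(levels=levels, parent=parents, perm=perm, fake_mask=fake_masks)


def polar_hierarchy(n_levels: int = 3, seed: int = 0) -> GraphHierarchy:
    """Coarsening hierarchy of the standard 460-node polar graph."""
    return coarsen(build_polar_adjacency(), n_levels=n_levels, seed=seed)


# ---------------------------------------------------------------------------
# Serialization: JSON metadata + per-level CSV edge lists, for caching
# ---------------------------------------------------------------------------


def save_hierarchy(hierarchy: GraphHierarchy, directory) -> None:
    """Write a hierarchy as hierarchy.json + level{k}_edges.csv files."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    meta = {
        "n_levels": hierarchy.n_levels,
        "perm": hierarchy.perm.tolist(),
        "parent": [p.tolist() for p in hierarchy.parent],
        "fake_mask": [m.astype(int).tolist() for m in hierarchy.fake_mask],
        "level_sizes": [lv.n for lv in hierarchy.levels],
    }
    with open(os.path.join(directory, "hierarchy.json"), "w") as fh:
        json.dump(meta, fh)
    for k, lv in enumerate(hierarchy.levels):
        coo = lv.adjacency.tocoo()
        keep = coo.row < coo.col  # undirected: store each edge once
        with open(os.path.join(directory, f"level{k}_edges.csv"), "w") as fh:
            fh.write("source,target,weight\n")
            for i, j, w in zip(coo.row[keep], coo.col[keep], coo.data[keep]):
                fh.write(f"{i},{j},{w}\n")


def load_hierarchy(directory) -> GraphHierarchy:
    """Rebuild a hierarchy saved by :func:`save_hierarchy`."""
    import csv
    import json
    import os

    with open(os.path.join(directory, "hierarchy.json")) as fh:
        meta = json.load(fh)
    levels = []
    for k, n in enumerate(meta["level_sizes"]):
        rows, cols, data = [], [], []
        with open(os.path.join(directory, f"level{k}_edges.csv")) as fh:
            for rec in csv.DictReader(fh):
                rows.append(int(rec["source"]))
                cols.append(int(rec["target"]))
                data.append(float(rec["weight"]))
        A = sp.coo_matrix((data + data, (rows + cols, cols + rows)), shape=(n, n))
        levels.append(make_graph(A.tocsr()))
    return GraphHierarchy(
        levels=levels,
        parent=[np.array(p, dtype=int) for p in meta["parent"]],
        perm=np.array(meta["perm"], dtype=int),
        fake_mask=[np.array(m, dtype=bool) for m in meta["fake_mask"]],
    )
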