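"""Haplotype networks: minimum-spanning network and median-joining (eps = 0).

The minimum-spanning network (MSN) is the union of all minimum spanning
trees: Kruskal over increasing distances, adding *every* inter-component
pair at the current distance before merging components ("equal-weight
closure").

Median joining iterates: build the MSN over the current node set; for node
triplets connected in it, propose the site-wise majority median; add the
median that most reduces the total network cost (MST weight of the extended
node set); repeat to a fixpoint, then drop unsampled medians of degree < 3.
With three distinct states at a site the majority vote can tie; ties resolve
to the state of the first node of the triplet in input order, making output
deterministic.  Node/edge insertion follows lexicographic haplotype id so
serialized networks are byte-stable.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from .alignment import HaplotypeTable, MISSING

__all__ = [
    "hamming_matrix",
    "minimum_spanning_network",
    "median_joining",
    "write_edges_tsv",
    "write_graphml",
]


def _as_seq_dict(haps) -> dict[str, str]:
    if isinstance(haps, HaplotypeTable):
        return dict(haps.representatives)
    return dict(haps)


def _complete_site_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Restrict to sites non-missing in every haplotype; sorted ids."""
    ids = sorted(seqs)
    data = np.frombuffer("".join(seqs[i] for i in ids).encode(), dtype="S1")
    data = data.reshape(len(ids), -1).copy()
    keep = ~np.isin(data, MISSING).any(axis=0)
    if not keep.any():
        raise ValueError("no sites free of missing data across all haplotypes")
    return ids, data[:, keep]


def hamming_matrix(haps) -> tuple[list[str], np.ndarray]:
    """Pairwise Hamming distances between haplotype representatives.

    Sites with missing data in any haplotype are excluded first, so the
    distances are exact mutation counts on the shared complete sites.
    Returns ``(ids, matrix)`` with ids sorted lexicographically.
    """
    ids, data = _complete_site_matrix(_as_seq_dict(haps))
    return ids, _dist(data)


def _dist(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i, i + 1:] = (data[i] != data[i + 1:]).sum(axis=1)
    return d + d.T


def _merge_identical(seqs: dict[str, str]) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Merge haplotypes indistinguishable on the shared complete sites.

    Restricting to sites complete in all haplotypes can make two distinct
    haplotypes identical; they become one node labelled ``a+b`` so every
    network edge keeps weight >= 1.  Returns (merged seqs, node -> members).
    """
    ids, data = _complete_site_matrix(seqs)
    buckets: dict[bytes, list[str]] = {}
    for h, row in zip(ids, data):
        buckets.setdefault(row.tobytes(), []).append(h)
    merged, members = {}, {}
    for key, group in buckets.items():
        node = "+".join(sorted(group))
        merged[node] = key.decode()
        members[node] = sorted(group)
    return merged, members


def _msn_graph(ids, dist: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(ids)
    if len(ids) < 2:
        return g
    pos = {h: i for i, h in enumerate(ids)}
    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = sorted(
        combinations(ids, 2),
        key=lambda p: (dist[pos[p[0]], pos[p[1]]], p),
    )
    i = 0
    while i < len(pairs):
        d = dist[pos[pairs[i][0]], pos[pairs[i][1]]]
        batch = []
        while i < len(pairs) and dist[pos[pairs[i][0]], pos[pairs[i][1]]] == d:
            batch.append(pairs[i])
            i += 1
        if d == 0:
            continue  # identical representatives should have been collapsed
        # add every inter-component pair at this distance, then merge
        added = [(a, b) for a, b in batch if find(a) != find(b)]
        for a, b in added:
            g.add_edge(a, b, weight=int(d))
        for a, b in added:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    return g


def minimum_spanning_network(haps, counts: dict[str, dict[str, int]] | None = None) -> nx.Graph:
    """Equal-weight-closed MSN over haplotype representatives.

    ``counts`` optionally maps haplotype id -> per-group sample counts,
    stored on nodes; nodes default to ``kind="sampled"``.  Haplotypes
    identical on the shared complete sites are merged into one node.
    """
    seqs, members = _merge_identical(_as_seq_dict(haps))
    ids, data = _complete_site_matrix(seqs)
    g = _msn_graph(ids, _dist(data))
    for h, row in zip(ids, data):
        g.nodes[h]["sequence"] = row.tobytes().decode()
    _annotate(g, counts, members)
    g.graph["epsilon"] = 0
    return g


def _annotate(g: nx.Graph, counts, members: dict[str, list[str]] | None = None) -> None:
    for node in g.nodes:
        g.nodes[node].setdefault("kind", "sampled")
        if counts is None:
            continue
        srcs = members.get(node, [node]) if members else [node]
        tally: dict[str, int] = {}
        for h in srcs:
            for grp, c in counts.get(h, {}).items():
                tally[grp] = tally.get(grp, 0) + int(c)
        for grp, c in tally.items():
            g.nodes[node][f"count_{grp}"] = c


def _mst_weight(ids, dist) -> int:
    """Total weight of a minimum spanning tree (Prim)."""
    n = len(ids)
    if n < 2:
        return 0
    in_tree = np.zeros(n, dtype=bool)
    best = dist[0].astype(float).copy()
    in_tree[0] = True
    best[0] = np.inf
    total = 0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += int(best[j])
        in_tree[j] = True
        best = np.minimum(best, dist[j].astype(float))
        best[in_tree] = np.inf
    return total


def _majority_median(rows: np.ndarray) -> bytes:
    """Site-wise majority of three sequences; ties -> first row's state."""
    a, b, c = rows
    med = a.copy()
    med[b == c] = b[b == c]  # two agreeing non-first states win
    return med.tobytes()


def median_joining(haps, epsilon: int = 0, counts=None) -> nx.Graph:
    """Median-joining network with the relaxation parameter fixed at 0.

    Raises if no fixpoint is reached within ``10 * K`` median additions.
    """
    if epsilon != 0:
        raise NotImplementedError("only epsilon = 0 is supported")
    seqs, members = _merge_identical(_as_seq_dict(haps))
    sampled = set(seqs)
    ids, data = _complete_site_matrix(seqs)
    arr = {h: data[i] for i, h in enumerate(ids)}
    K = len(ids)
    max_iter = 10 * max(K, 1)
    n_medians = 0

    for _ in range(max_iter + 1):
        order = sorted(arr)
        mat = np.stack([arr[h] for h in order])
        dist = _dist(mat)
        msn = _msn_graph(order, dist)
        base_cost = _mst_weight(order, dist)

        existing = {a.tobytes() for a in arr.values()}
        best = None  # (cost, seq_bytes)
        for u, v in msn.edges:
            for w in order:
                if w in (u, v):
                    continue
                if not (msn.has_edge(u, w) or msn.has_edge(v, w)):
                    continue
                trip = sorted((u, v, w))  # first node in id order breaks ties
                med = _majority_median(np.stack([arr[t] for t in trip]))
                if med in existing:
                    continue
                med_arr = np.frombuffer(med, dtype="S1")
                ext = np.zeros((len(order) + 1, len(order) + 1), dtype=np.int64)
                ext[:-1, :-1] = dist
                dm = (mat != med_arr).sum(axis=1)
                ext[-1, :-1] = dm
                ext[:-1, -1] = dm
                cost = _mst_weight(order + ["__med__"], ext)
                if cost < base_cost and (best is None or (cost, med) < best):
                    best = (cost, med)
        if best is None:
            break
        n_medians += 1
        arr[f"mv{n_medians}"] = np.frombuffer(best[1], dtype="S1")
    else:
        raise RuntimeError(
            f"median-joining did not converge within {max_iter} iterations "
            f"({len(sampled)} haplotypes)"
        )

    # prune obsolete medians (unsampled, degree < 3), iterating to stability
    while True:
        order = sorted(arr)
        dist = _dist(np.stack([arr[h] for h in order]))
        g = _msn_graph(order, dist)
        drop = [h for h in order if h not in sampled and g.degree[h] < 3]
        if not drop:
            break
        for h in drop:
            del arr[h]

    for node in g.nodes:
        g.nodes[node]["kind"] = "sampled" if node in sampled else "median"
        g.nodes[node]["sequence"] = arr[node].tobytes().decode()
    _annotate(g, counts, members)
    g.graph["epsilon"] = 0
    return g


def write_edges_tsv(g: nx.Graph, path) -> None:
    """Edge list: ``node1<TAB>node2<TAB>mutations``, lexicographic order."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tmutations\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\t{g.edges[a, b]['weight']}\n")


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))
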