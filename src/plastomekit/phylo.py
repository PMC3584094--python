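"""Parsimony and distance phylogenetics at desk scale.

Fitch parsimony scoring (unordered characters, gaps as missing data),
consistency/retention indices, Saitou-Nei neighbor joining from a distance
matrix, a random-addition + NNI hill-climbing parsimony search (a small-
scale stand-in for TBR heuristics), and bootstrap support over bipartitions.

Trees are unrooted with binary internal nodes (degree 3); newick I/O goes
through dendropy. Exhaustive topology enumeration is provided so searches
can be validated against the global optimum for small taxon sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

_BASE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


class Tree:
    """An unrooted tree over labeled leaves, with optional branch lengths."""

    def __init__(self):
        self.adj: dict[int, dict[int, float | None]] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    # -- construction -----------------------------------------------------
    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float | None = None) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.label = dict(self.label)
        t._next = self._next
        return t

    @classmethod
    def star(cls, labels: list[str]) -> "Tree":
        """Three leaves around one internal node (the smallest unrooted tree)."""
        if len(labels) != 3:
            raise ValueError("star() wants exactly 3 labels")
        t = cls()
        c = t.new_node()
        for lab in labels:
            t.add_edge(c, t.new_node(lab))
        return t

    # -- queries -----------------------------------------------------------
    def leaves(self) -> list[int]:
        return sorted(n for n, nb in self.adj.items() if len(nb) == 1 and n in self.label)

    def leaf_labels(self) -> list[str]:
        return sorted(self.label[n] for n in self.leaves())

    def edges(self) -> list[tuple[int, int]]:
        return sorted((min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v)

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v in self.edges()
                if len(self.adj[u]) > 1 and len(self.adj[v]) > 1]

    def _side_labels(self, u: int, v: int) -> frozenset:
        """Leaf labels on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        labs = []
        while stack:
            x = stack.pop()
            if x in self.label:
                labs.append(self.label[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(labs)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, canonicalized to the side not containing the
        smallest leaf label."""
        all_labels = set(self.leaf_labels())
        ref = min(all_labels)
        out = set()
        for u, v in self.internal_edges():
            side = self._side_labels(u, v)
            if ref in side:
                side = frozenset(all_labels - side)
            if 2 <= len(side) <= len(all_labels) - 2:
                out.add(side)
        return out

    def same_topology(self, other: "Tree") -> bool:
        return (self.leaf_labels() == other.leaf_labels()
                and self.bipartitions() == other.bipartitions())

    # -- newick ------------------------------------------------------------
    def newick(self, lengths: bool = True) -> str:
        root = max(self.adj, key=lambda n: (len(self.adj[n]), -n))

        def rec(node, parent):
            kids = [c for c in sorted(self.adj[node]) if c != parent]
            if not kids:
                s = self.label.get(node, str(node))
            else:
                s = "(" + ",".join(rec(c, node) for c in kids) + ")"
            if parent is not None and lengths:
                bl = self.adj[node][parent]
                if bl is not None:
                    s += f":{bl:.6g}"
            return s

        return rec(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")
        dt.migrate_taxon_namespace(dendropy.TaxonNamespace())
        t = cls()
        ids: dict = {}
        for nd in dt.preorder_node_iter():
            lab = nd.taxon.label if nd.taxon is not None else None
            ids[nd] = t.new_node(lab)
            if nd.parent_node is not None:
                t.add_edge(ids[nd.parent_node], ids[nd], nd.edge.length)
        # unroot: collapse a degree-2 root
        root = ids[dt.seed_node]
        if len(t.adj[root]) == 2:
            (a, la), (b, lb) = t.adj[root].items()
            t.remove_edge(root, a)
            t.remove_edge(root, b)
            del t.adj[root]
            t.add_edge(a, b, (la or 0) + (lb or 0) if (la is not None or lb is not None) else None)
        return t


# ---------------------------------------------------------------------------
# Fitch parsimony


def _leaf_masks(alignment: dict[str, str]) -> tuple[dict[str, np.ndarray], int]:
    lens = {len(v) for v in alignment.values()}
    if len(lens) != 1:
        raise ValueError("alignment rows differ in length")
    L = lens.pop()
    masks = {}
    for taxon, row in alignment.items():
        m = np.full(L, _MISSING, dtype=np.uint8)
        for i, ch in enumerate(row.upper()):
            m[i] = _BASE_MASK.get(ch, _MISSING)
        masks[taxon] = m
    return masks, L


def _postorder(tree: Tree, root: int) -> list[tuple[int, int | None]]:
    order = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for c in sorted(tree.adj[node]):
            if c != parent:
                stack.append((c, node))
    return order[::-1]


def fitch_length(tree: Tree, alignment: dict[str, str], site_weights=None) -> int:
    """Fitch tree length: minimal unordered changes summed over sites.

    Gaps and ambiguity codes are missing data (full state set, contributing
    no changes). Every leaf label must appear in the alignment.
    """
    for lab in tree.leaf_labels():
        if lab not in alignment:
            raise ValueError(f"leaf {lab!r} missing from the alignment")
    masks, L = _leaf_masks(alignment)
    w = np.ones(L, dtype=np.int64) if site_weights is None else np.asarray(site_weights)
    root = max(tree.adj, key=lambda n: (len(tree.adj[n]), -n))
    state: dict[int, np.ndarray] = {}
    steps = 0
    for node, parent in _postorder(tree, root):
        kids = [c for c in tree.adj[node] if c != parent]
        if not kids:
            state[node] = masks[tree.label[node]]
            continue
        acc = state[kids[0]]
        for c in kids[1:]:
            inter = acc & state[c]
            empty = inter == 0
            steps += int(w[empty].sum())
            acc = np.where(empty, acc | state[c], inter)
        state[node] = acc
    return steps


@dataclass(frozen=True)
class ParsimonyResult:
    """Tree length with homoplasy indices.

    CI = M/L (minimum conceivable steps over observed steps) and
    RI = (G-L)/(G-M); both None when undefined (constant data, or G == M).
    """

    length: int
    min_steps: int
    max_steps: int
    ci: float | None
    ri: float | None


def _site_mg(alignment: dict[str, str]):
    masks, L = _leaf_masks(alignment)
    stack = np.vstack([masks[t] for t in sorted(alignment)])
    has_data = stack != _MISSING
    freqs = np.stack([((stack == v) & has_data).sum(axis=0)
                      for v in (1, 2, 4, 8)])  # 4 x L
    n_data = has_data.sum(axis=0)
    n_states = (freqs > 0).sum(axis=0)
    m = np.maximum(n_states - 1, 0)
    g = np.where(n_data > 0, n_data - freqs.max(axis=0), 0)
    informative = (freqs >= 2).sum(axis=0) >= 2
    gapped = (~has_data).any(axis=0)
    return m, g, informative, gapped


def ci_ri(
    tree: Tree,
    alignment: dict[str, str],
    include_uninformative: bool = True,
    exclude_gapped: bool = False,
) -> ParsimonyResult:
    """Consistency and retention indices of an alignment on a tree.

    Per site, the minimum steps m is (observed states - 1) and the maximum
    g is (taxa with data - most frequent state count). Uninformative sites
    are included by default; ``exclude_gapped`` drops columns containing
    any gap/ambiguity before scoring.
    """
    m, g, informative, gapped = _site_mg(alignment)
    keep = np.ones(m.size, dtype=bool)
    if exclude_gapped:
        keep &= ~gapped
    if not include_uninformative:
        keep &= informative
    weights = keep.astype(np.int64)
    L = fitch_length(tree, alignment, site_weights=weights)
    M = int(m[keep].sum())
    G = int(g[keep].sum())
    ci = (M / L) if L > 0 else None
    ri = ((G - L) / (G - M)) if G > M else None
    return ParsimonyResult(length=L, min_steps=M, max_steps=G, ci=ci, ri=ri)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(labels: list[str], dist) -> Tree:
    """Saitou-Nei neighbor joining.

    ``dist`` is a symmetric matrix with zero diagonal in the order of
    ``labels``. Ties in the Q criterion break deterministically by label
    order; negative branch lengths are clamped to zero. Exact on additive
    matrices.
    """
    D = np.asarray(dist, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    t = Tree()
    nodes = [t.new_node(lab) for lab in labels]
    reps = list(labels)  # representative (smallest) label per cluster
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(k), 2):
            q = (k - 2) * sub[ai, aj] - r[ai] - r[aj]
            key = (q, *sorted((reps[active[ai]], reps[active[aj]])))
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2))
        lj = dij - li
        u = t.new_node()
        t.add_edge(u, nodes[i], max(li, 0.0))
        t.add_edge(u, nodes[j], max(lj, 0.0))
        # distances from the new cluster
        newrow = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for m_ in active:
            if m_ in (i, j):
                continue
            D[-1, m_] = D[m_, -1] = 0.5 * (D[i, m_] + D[j, m_] - dij)
        nodes.append(u)
        reps.append(min(reps[i], reps[j]))
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]
    # connect the last three
    a, b, c = active
    x = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    y = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    z = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    u = t.new_node()
    t.add_edge(u, nodes[a], max(x, 0.0))
    t.add_edge(u, nodes[b], max(y, 0.0))
    t.add_edge(u, nodes[c], max(z, 0.0))
    return t


def tree_distance_matrix(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Path-length (additive) distances between all leaf pairs."""
    leaves = tree.leaves()
    labels = [tree.label[x] for x in leaves]
    order = np.argsort(labels)
    leaves = [leaves[i] for i in order]
    labels = [labels[i] for i in order]
    n = len(leaves)
    D = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, bl in tree.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + (bl or 0.0)
                    stack.append(y)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    D = (D + D.T) / 2.0  # remove float asymmetry from per-source summation
    np.fill_diagonal(D, 0.0)
    return labels, D


# ---------------------------------------------------------------------------
# parsimony search


def _insert_leaf(tree: Tree, edge: tuple[int, int], label: str) -> tuple[int, int]:
    u, v = edge
    tree.remove_edge(u, v)
    w = tree.new_node()
    leaf = tree.new_node(label)
    tree.add_edge(u, w)
    tree.add_edge(v, w)
    tree.add_edge(w, leaf)
    return w, leaf


def enumerate_topologies(labels: list[str]):
    """Yield every unrooted binary topology over the labels ((2n-5)!! trees)."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")

    def rec(tree: Tree, remaining: list[str]):
        if not remaining:
            yield tree
            return
        lab, rest = remaining[0], remaining[1:]
        for edge in tree.edges():
            t2 = tree.copy()
            _insert_leaf(t2, edge, lab)
            yield from rec(t2, rest)

    yield from rec(Tree.star(labels[:3]), labels[3:])


def _nni_neighbors(tree: Tree):
    """All trees one nearest-neighbor interchange away (2 per internal edge)."""
    for u, v in tree.internal_edges():
        a_nbrs = sorted(x for x in tree.adj[u] if x != v)
        c_nbrs = sorted(x for x in tree.adj[v] if x != u)
        if len(a_nbrs) != 2 or len(c_nbrs) != 2:
            continue
        b = a_nbrs[1]
        for c in c_nbrs:
            t2 = tree.copy()
            t2.remove_edge(u, b)
            t2.remove_edge(v, c)
            t2.add_edge(u, c)
            t2.add_edge(v, b)
            yield t2


def search_mp(
    alignment: dict[str, str], n_starts: int = 10, seed: int = 0
) -> tuple[Tree, ParsimonyResult]:
    """Parsimony search: random-addition starts followed by NNI hill
    climbing; deterministic under the seed. Returns the best tree found
    with its length/CI/RI."""
    labels = sorted(alignment)
    if len(labels) < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))
    best_tree = None
    best_len = math.inf
    for _ in range(n_starts):
        order = [labels[i] for i in rng.permutation(len(labels))]
        tree = Tree.star(order[:3])
        for lab in order[3:]:
            cand_best = None
            for edge in tree.edges():
                t2 = tree.copy()
                _insert_leaf(t2, edge, lab)
                ln = fitch_length(t2, alignment)
                if cand_best is None or ln < cand_best[0]:
                    cand_best = (ln, t2)
            tree = cand_best[1]
        cur_len = fitch_length(tree, alignment)
        improved = True
        while improved:
            improved = False
            for t2 in _nni_neighbors(tree):
                ln = fitch_length(t2, alignment)
                if ln < cur_len:
                    tree, cur_len = t2, ln
                    improved = True
                    break
        if cur_len < best_len:
            best_tree, best_len = tree, cur_len
    return best_tree, ci_ri(best_tree, alignment)


def bootstrap_support(
    alignment: dict[str, str], builder, n_reps: int = 100, seed: int = 0
) -> dict[frozenset, float]:
    """Bootstrap percentages for the bipartitions of the point-estimate tree.

    Sites are resampled with replacement; ``builder`` maps an alignment to a
    Tree (e.g. a search_mp or nj wrapper).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = builder(alignment)
    splits = point.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    L = len(next(iter(alignment.values())))
    taxa = list(alignment)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        resampled = {t: "".join(alignment[t][i] for i in idx) for t in taxa}
        reps = builder(resampled).bipartitions()
        for s in splits:
            if s in reps:
                counts[s] += 1
    return {s: 100.0 * c / n_reps for s, c in counts.items()}
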