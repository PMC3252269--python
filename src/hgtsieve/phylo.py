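"""Distance-based protein phylogenetics: p/Kimura distances, BIONJ, bootstrap.

The tree machinery is deliberately distance-based and closed-form: pairwise
protein distances under the p-distance or Kimura's empirical correction
``d = -ln(1 - p - 0.2 p^2)``, BIONJ agglomeration (variance-weighted
neighbor joining), nonparametric bootstrap over alignment columns, and
deterministic midpoint rooting.  Externally built trees (e.g. Bayesian or
maximum-likelihood Newick with support labels) are accepted through
:func:`read_newick` and flow through the same downstream classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

#: Distance assigned to saturated pairs (p >= SATURATION_P) under the
#: Kimura correction, in substitutions/site.
SATURATION_CAP = 10.0
SATURATION_P = 0.85

_GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# GeneTree wrapper

class GeneTree:
    """A gene tree: dendropy topology plus per-leaf species/group labels.

    Branch lengths are in expected substitutions/site; internal node labels
    hold bootstrap supports (percent) when present.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        groups: Optional[Mapping[str, str]] = None,
        species: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.tree = tree
        self.groups: Dict[str, str] = dict(groups or {})
        self.species: Dict[str, str] = dict(species or {})

    # -- basic accessors ----------------------------------------------------
    def leaf_ids(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __contains__(self, leaf_id: str) -> bool:
        return leaf_id in set(self.leaf_ids())

    def annotate(self, species_map: Mapping[str, Tuple[str, str]]) -> "GeneTree":
        """Attach species/group labels from an id -> (species, group) map."""
        for leaf_id in self.leaf_ids():
            if leaf_id in species_map:
                sp, grp = species_map[leaf_id]
                self.species[leaf_id] = sp
                self.groups[leaf_id] = grp
        return self

    def clone(self) -> "GeneTree":
        return GeneTree(self.tree.clone(depth=1), dict(self.groups), dict(self.species))

    def newick(self) -> str:
        text = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return text

    def support_of(self, node: dendropy.Node) -> Optional[float]:
        if node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None


def read_newick(source: Union[str, Path]) -> GeneTree:
    """Parse Newick from a string or file path into a GeneTree.

    Internal node labels (e.g. bootstrap percentages) are preserved as
    support labels.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and not source.rstrip().endswith(";") and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick: {exc}") from exc
    tree.suppress_unifurcations()
    return GeneTree(tree)


def write_newick(tree: GeneTree, path: Optional[Union[str, Path]] = None) -> str:
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Distance matrices

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over an ordered taxon list."""

    ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{name}  {row}\n")

    @classmethod
    def from_phylip(cls, path: Union[str, Path]) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids, np.array(rows))


def _as_rows(alignment) -> Tuple[List[str], List[str]]:
    ids, seqs = [], []
    for row in alignment:
        if hasattr(row, "residues"):
            ids.append(row.id)
            seqs.append(row.residues)
        else:
            ids.append(row[0])
            seqs.append(row[1])
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return ids, seqs


def kimura_correction(p: np.ndarray) -> np.ndarray:
    """Kimura's empirical protein distance ``-ln(1 - p - 0.2 p^2)``.

    Saturated entries (p >= 0.85) receive :data:`SATURATION_CAP`.
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -np.log(1.0 - p - 0.2 * p * p)
    d = np.where(p >= SATURATION_P, SATURATION_CAP, d)
    return np.minimum(d, SATURATION_CAP)


def protein_distance_matrix(alignment, model: str = "kimura") -> DistanceMatrix:
    """Pairwise distances from an aligned set of protein sequences.

    Gap columns are deleted pairwise; ``model`` is ``p`` (raw proportion of
    differing sites) or ``kimura``.  A pair with zero comparable columns is an
    error naming the pair.
    """
    if model not in ("p", "kimura"):
        raise ValueError(f"unknown distance model {model!r}")
    ids, seqs = _as_rows(alignment)
    arr = np.array([list(s) for s in seqs])
    is_gap = np.isin(arr, list(_GAP_CHARS))
    n = len(ids)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            p[i, j] = p[j, i] = np.count_nonzero(arr[i, ok] != arr[j, ok]) / m
    d = kimura_correction(p) if model == "kimura" else p
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# BIONJ

def bionj(matrix: DistanceMatrix) -> GeneTree:
    """BIONJ agglomeration (variance-weighted neighbor joining).

    Follows the classical scheme: the NJ Q-criterion selects the pair to
    join; the reduced distance to the new node is a convex combination
    weighted to minimise the variance of the reduced matrix, with the
    variance matrix initialised to the distances and reduced alongside.
    Negative branch estimates are clamped to zero.  Ties on the Q-criterion
    are broken toward the lexicographically smallest id pair, which makes
    the output deterministic.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("BIONJ needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(matrix.ids)
    nodes: List[dendropy.Node] = []
    for label in matrix.ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)
    names = list(matrix.ids)
    D = matrix.values.copy()
    V = matrix.values.copy()  # variance proxy, reduced alongside D

    while len(nodes) > 3:
        r = len(nodes)
        S = D.sum(axis=1)
        Q = (r - 2) * D - S[:, None] - S[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best: Optional[Tuple[str, str, int, int]] = None
        for i in range(r):
            for j in range(i + 1, r):
                if Q[i, j] <= qmin + 1e-10:
                    key = tuple(sorted((names[i], names[j])))
                    if best is None or key < best[:2]:
                        best = (key[0], key[1], i, j)
        assert best is not None
        i, j = best[2], best[3]

        bi = 0.5 * D[i, j] + (S[i] - S[j]) / (2 * (r - 2))
        bj = D[i, j] - bi
        bi, bj = max(bi, 0.0) + 0.0, max(bj, 0.0) + 0.0

        mask = np.ones(r, dtype=bool)
        mask[[i, j]] = False
        if V[i, j] > 0:
            lam = 0.5 + (V[j, mask] - V[i, mask]).sum() / (2 * (r - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        new_d = lam * (D[i, mask] - bi) + (1 - lam) * (D[j, mask] - bj)
        new_d = np.maximum(new_d, 0.0)
        new_v = lam * V[i, mask] + (1 - lam) * V[j, mask] - lam * (1 - lam) * V[i, j]
        new_v = np.maximum(new_v, 0.0)

        parent = dendropy.Node()
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        keep = [k for k in range(r) if mask[k]]
        nodes = [nodes[k] for k in keep] + [parent]
        new_name = min(names[i], names[j])  # stable key for tie-breaking
        names = [names[k] for k in keep] + [new_name]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_d
        V2 = np.zeros((r - 1, r - 1))
        V2[:-1, :-1] = V[np.ix_(keep, keep)]
        V2[-1, :-1] = V2[:-1, -1] = new_v
        D, V = D2, V2

    # three-point closure: trifurcating base
    (x, y, z) = nodes
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    x.edge.length = max(0.0, 0.5 * (dxy + dxz - dyz))
    y.edge.length = max(0.0, 0.5 * (dxy + dyz - dxz))
    z.edge.length = max(0.0, 0.5 * (dxz + dyz - dxy))
    base = dendropy.Node()
    for nd in nodes:
        base.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = base
    tree.is_rooted = False
    return GeneTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap

def _bipartitions(gtree: GeneTree) -> Dict[frozenset, dendropy.Node]:
    """Internal-edge bipartitions as normalised leaf-id frozensets."""
    all_leaves = frozenset(gtree.leaf_ids())
    ref = min(all_leaves)
    out: Dict[frozenset, dendropy.Node] = {}
    for node in gtree.tree.preorder_node_iter():
        if node.is_leaf() or node is gtree.tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(all_leaves - below) <= 1:
            continue
        key = below if ref not in below else all_leaves - below
        out[key] = node
    return out


def default_tree_builder(alignment) -> GeneTree:
    return bionj(protein_distance_matrix(alignment, model="kimura"))


def bootstrap_support(
    alignment,
    tree_builder: Callable[[Sequence[Tuple[str, str]]], GeneTree] = default_tree_builder,
    n_replicates: int = 1000,
    seed: int = 0,
) -> GeneTree:
    """Column-resampling bootstrap; supports as percent on internal nodes.

    Supports count, for every internal bipartition of the point-estimate
    tree, the fraction of replicate trees containing that bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, seqs = _as_rows(alignment)
    ncols = len(seqs[0])
    if ncols < 2:
        raise ValueError("alignment must have at least 2 columns")
    point = tree_builder(list(zip(ids, seqs)))
    target = _bipartitions(point)
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    cols = np.array([list(s) for s in seqs])
    for _ in range(n_replicates):
        idx = rng.integers(0, ncols, size=ncols)
        rep_rows = ["".join(row) for row in cols[:, idx]]
        try:
            rep = tree_builder(list(zip(ids, rep_rows)))
        except ValueError:
            continue  # e.g. a replicate with no comparable columns for a pair
        rep_bips = set(_bipartitions(rep))
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    for key, node in target.items():
        node.label = str(round(100.0 * counts[key] / n_replicates))
    return point


# ---------------------------------------------------------------------------
# Midpoint rooting

def _adjacency(tree: dendropy.Tree):
    adj: Dict[dendropy.Node, List[Tuple[dendropy.Node, float, dendropy.Edge]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w, child.edge))
            adj.setdefault(child, []).append((node, w, child.edge))
    return adj


def midpoint_root(gtree: GeneTree) -> GeneTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken toward the lexicographically
    smallest (sorted) leaf pair.  A tree whose branch lengths are all zero is
    returned rooted at its designated base with a warning.
    """
    gtree = gtree.clone()
    tree = gtree.tree
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    adj = _adjacency(tree)

    total = sum(w for pairs in adj.values() for (_, w, _) in pairs)
    if total == 0:
        warnings.warn("all branch lengths zero; rooting at designated base", stacklevel=2)
        tree.is_rooted = True
        return gtree

    # single-source path lengths + predecessors from each leaf
    best: Optional[Tuple[float, Tuple[str, str]]] = None
    dist_from: Dict[str, Dict[dendropy.Node, float]] = {}
    pred_from: Dict[str, Dict[dendropy.Node, dendropy.Node]] = {}
    for label, src in leaves.items():
        dist: Dict[dendropy.Node, float] = {src: 0.0}
        pred: Dict[dendropy.Node, dendropy.Node] = {}
        stack = [src]
        while stack:
            nd = stack.pop()
            for (nb, w, _) in adj[nd]:
                if nb not in dist:
                    dist[nb] = dist[nd] + w
                    pred[nb] = nd
                    stack.append(nb)
        dist_from[label] = dist
        pred_from[label] = pred
    for a in sorted(leaves):
        for b in sorted(leaves):
            if a >= b:
                continue
            d = dist_from[a][leaves[b]]
            cand = (d, (a, b))
            if best is None or d > best[0] + 1e-12 or (abs(d - best[0]) <= 1e-12 and cand[1] < best[1]):
                best = cand
    assert best is not None
    dmax, (a, b) = best

    # walk the a->b path to the half-way point
    path: List[dendropy.Node] = [leaves[b]]
    while path[-1] is not leaves[a]:
        path.append(pred_from[a][path[-1]])
    path.reverse()  # a ... b
    half = dmax / 2.0
    acc = 0.0
    for u, v in zip(path, path[1:]):
        w = dist_from[a][v] - dist_from[a][u]
        if acc + w >= half - 1e-12:
            # midpoint lies on edge (u, v)
            into_edge = half - acc
            edge = v.edge if v.parent_node is u else u.edge
            if v.parent_node is u:
                l_child = (edge.length or 0.0) - into_edge
                l_parent = into_edge
            else:
                l_child = into_edge
                l_parent = (edge.length or 0.0) - into_edge
            tree.reroot_at_edge(edge, length1=max(l_parent, 0.0), length2=max(l_child, 0.0))
            tree.is_rooted = True
            return gtree
        acc += w
    # numerical fallthrough: root at b's edge
    tree.reroot_at_edge(leaves[b].edge, update_bipartitions=False)
    tree.is_rooted = True
    return gtree
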