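"""Comparative genomics of MTase repertoires.

Presence/absence profiling from ortholog-identity tables (strict >70%
identity by default), persistence, Jaccard distances, UPGMA and
neighbor-joining trees, and single-linkage species clustering on genome
distances (D ~ 1 - ANI, same-species threshold 0.06).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PresenceAbsenceMatrix:
    mtase_ids: list[str]
    genome_ids: list[str]
    cells: np.ndarray  # bool, MTase x genome

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != (len(self.mtase_ids), len(self.genome_ids)):
            raise ValueError("cell matrix shape does not match id lists")
        if self.cells.size and not self.cells.any(axis=1).all():
            raise ValueError("all-absent MTase row")

    def profile(self, mtase_id: str) -> np.ndarray:
        return self.cells[self.mtase_ids.index(mtase_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.mtase_ids,
                            columns=self.genome_ids)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.isnan(self.d).any():
            raise ValueError("NaN distance")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("non-zero diagonal")
        if (self.d < 0).any():
            raise ValueError("negative distance")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(ids=[str(c) for c in frame.columns], d=frame.to_numpy(float))

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


@dataclass
class TreeNode:
    """Minimal rooted tree node; children carry their branch lengths."""

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child, _bl in self.children for leaf in child.leaves()]

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                depths[node.name] = depth
            for child, bl in node.children:
                walk(child, depth + bl)

        walk(self, 0.0)
        return depths

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths through the tree."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = walk(child)
                below.append({leaf: d + bl for leaf, d in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self)
        return dists

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(
                f"{fmt(child)}:{bl:.6g}" for child, bl in node.children
            )
            return f"({inner})"

        return fmt(self) + ";"


# ---------------------------------------------------------------------------
# Presence/absence
# ---------------------------------------------------------------------------

def build_presence_absence(
    hits: Union[pd.DataFrame, Iterable[tuple[str, str, float]]],
    threshold: float = 70.0,
    source_genomes: Optional[Mapping[str, str]] = None,
    ortholog_groups: Optional[Mapping[str, str]] = None,
) -> PresenceAbsenceMatrix:
    """Presence/absence matrix from (queryMtase, genome, percentIdentity) hits.

    A cell is present iff some hit exceeds *threshold* strictly.  A query's
    own genome (from *source_genomes*) is always present.  *ortholog_groups*
    optionally merges mutually orthologous queries into one row keyed by the
    lexicographically smallest member id.  All-absent rows are dropped with a
    warning.
    """
    if isinstance(hits, pd.DataFrame):
        triples = list(hits.itertuples(index=False, name=None))
    else:
        triples = list(hits)
    for _q, _g, ident in triples:
        if not 0.0 <= float(ident) <= 100.0:
            raise ValueError(f"percent identity {ident} outside [0, 100]")

    def row_key(query: str) -> str:
        return ortholog_groups.get(query, query) if ortholog_groups else query

    mtases = sorted({row_key(q) for q, _g, _i in triples}
                    | {row_key(q) for q in (source_genomes or {})})
    genomes = sorted({g for _q, g, _i in triples}
                     | set((source_genomes or {}).values()))
    cells = np.zeros((len(mtases), len(genomes)), dtype=bool)
    m_index = {m: i for i, m in enumerate(mtases)}
    g_index = {g: j for j, g in enumerate(genomes)}
    for query, genome, ident in triples:
        if float(ident) > threshold:
            cells[m_index[row_key(query)], g_index[genome]] = True
    for query, genome in (source_genomes or {}).items():
        cells[m_index[row_key(query)], g_index[genome]] = True

    present = cells.any(axis=1)
    if not present.all():
        dropped = [m for m, keep in zip(mtases, present) if not keep]
        logger.warning("dropping MTases with no presence anywhere: %s", dropped)
        mtases = [m for m, keep in zip(mtases, present) if keep]
        cells = cells[present]
    return PresenceAbsenceMatrix(mtase_ids=mtases, genome_ids=genomes, cells=cells)


def persistent_mtases(matrix: PresenceAbsenceMatrix) -> list[str]:
    """MTases present in every genome of the panel."""
    if not matrix.genome_ids:
        raise ValueError("need at least one genome")
    keep = matrix.cells.all(axis=1)
    return [m for m, k in zip(matrix.mtase_ids, keep) if k]


def jaccard_distance(profile_a: Sequence[bool], profile_b: Sequence[bool]) -> float:
    """1 - |A n B| / |A u B|; two empty profiles are at distance 0."""
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profile length mismatch")
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return 1.0 - int((a & b).sum()) / union


def profile_distance_matrix(matrix: PresenceAbsenceMatrix,
                            axis: str = "mtase") -> DistanceMatrix:
    """Pairwise Jaccard distances between MTase rows (or genome columns)."""
    if axis == "mtase":
        ids, vectors = matrix.mtase_ids, matrix.cells
    elif axis == "genome":
        ids, vectors = matrix.genome_ids, matrix.cells.T
    else:
        raise ValueError("axis must be 'mtase' or 'genome'")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(vectors[i], vectors[j])
    return DistanceMatrix(ids=list(ids), d=d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def upgma(dist: DistanceMatrix) -> TreeNode:
    """UPGMA: merge the closest pair, size-weighted average distances.

    Node height is half the merge distance; ties break by the
    lexicographically smallest member id of the candidate pair.
    """
    if len(dist.ids) < 2:
        raise ValueError("UPGMA needs at least 2 ids")
    clusters: dict[int, tuple[TreeNode, int, float, str]] = {}
    # id -> (node, size, height, smallest member label)
    for i, name in enumerate(dist.ids):
        clusters[i] = (TreeNode(name=name), 1, 0.0, name)
    d = {frozenset((i, j)): float(dist.d[i, j])
         for i in clusters for j in clusters if i < j}
    next_id = len(dist.ids)
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(clusters[k][3] for k in kv[0])),
            ),
        )
        pair, dmin = best
        i, j = sorted(pair)
        node_i, size_i, h_i, lab_i = clusters.pop(i)
        node_j, size_j, h_j, lab_j = clusters.pop(j)
        height = dmin / 2.0
        parent = TreeNode(children=[
            (node_i, height - h_i), (node_j, height - h_j),
        ])
        for k in list(clusters):
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (
                (size_i * dik + size_j * djk) / (size_i + size_j)
            )
        d.pop(pair, None)
        clusters[next_id] = (parent, size_i + size_j, height, min(lab_i, lab_j))
        next_id += 1
    (root, _size, _h, _lab), = clusters.values()
    return root


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Returned unrooted topology is represented as a trifurcating root node.
    Ties in the Q matrix break toward the lexicographically smallest (i, j)
    label pair.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 ids; use upgma instead")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=name)
                                  for i, name in enumerate(dist.ids)}
    labels: dict[int, str] = dict(enumerate(dist.ids))
    d: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dist.d[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    branch: dict[int, float] = {}  # pending branch length toward parent
    active = set(range(n))
    next_id = n

    def dget(i: int, j: int) -> float:
        return 0.0 if i == j else d[frozenset((i, j))]

    while len(active) > 3:
        r = len(active)
        total = {i: sum(dget(i, k) for k in active) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                q = (r - 2) * dget(i, j) - total[i] - total[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _key, i, j = best
        dij = dget(i, j)
        li = 0.5 * dij + (total[i] - total[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        for k in active - {i, j}:
            dk = 0.5 * (dget(i, k) + dget(j, k) - dij)
            d[frozenset((next_id, k))] = max(dk, 0.0)
        nodes[next_id] = parent
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1

    i, j, k = sorted(active)
    li = 0.5 * (dget(i, j) + dget(i, k) - dget(j, k))
    lj = 0.5 * (dget(i, j) + dget(j, k) - dget(i, k))
    lk = 0.5 * (dget(i, k) + dget(j, k) - dget(i, j))
    return TreeNode(children=[
        (nodes[i], max(li, 0.0)),
        (nodes[j], max(lj, 0.0)),
        (nodes[k], max(lk, 0.0)),
    ])


def cluster_species(dist: DistanceMatrix, threshold: float = 0.06) -> list[set[str]]:
    """Single-linkage components of the graph with edges d <= threshold."""
    n = len(dist.ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist.d[i, j] <= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, name in enumerate(dist.ids):
        groups.setdefault(find(i), set()).add(name)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])
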