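"""Population tree from allele frequencies.

Euclidean distances between population frequency vectors, agglomerated by
Ward's minimum-variance method (Lance-Williams update on squared
distances, deterministic lexicographic tie-break), with clade support from
marker bootstrap.  Heights follow the scipy convention (Euclidean-scale
Ward distances), so trees can be cross-checked against
``scipy.cluster.hierarchy.linkage(..., 'ward')``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, PopulationPartition
from .popstats import allele_freq_table

__all__ = ["TreeNode", "PopulationTree", "frequency_matrix", "ward_tree", "bootstrap_support"]


@dataclass
class TreeNode:
    """Node of a rooted binary merge tree; leaves carry a population label."""

    label: str | None = None
    height: float = 0.0
    children: tuple["TreeNode", "TreeNode"] | None = None
    support: float | None = None  # percentage in [0, 100], internal nodes only

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return self.children[0].leaves() | self.children[1].leaves()

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes."""
        if self.is_leaf:
            return set()
        out = {self.leaves()}
        for ch in self.children:
            out |= ch.clades()
        return out

    def _newick(self, parent_height: float) -> str:
        blen = parent_height - self.height
        if self.is_leaf:
            return f"{self.label}:{blen:.10g}"
        inner = ",".join(ch._newick(self.height) for ch in self.children)
        sup = "" if self.support is None else f"{self.support:.4g}"
        return f"({inner}){sup}:{blen:.10g}"

    def to_newick(self) -> str:
        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(ch._newick(self.height) for ch in self.children)
        sup = "" if self.support is None else f"{self.support:.4g}"
        return f"({inner}){sup};"


@dataclass
class PopulationTree:
    root: TreeNode
    populations: list[str]
    n_bootstrap: int = 0

    def to_newick(self) -> str:
        return self.root.to_newick()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def clades(self) -> set[frozenset[str]]:
        return self.root.clades()


def frequency_matrix(
    gm: GenotypeMatrix, partition: PopulationPartition
) -> tuple[np.ndarray, list[str], int]:
    """Populations x markers allele_b frequency table.

    Markers where any population has no called genotypes are dropped.
    Returns (matrix, population labels, number of dropped markers).
    """
    table = allele_freq_table(gm, partition)
    freq = table.freq_b
    keep = np.isfinite(freq).all(axis=0)
    if freq.shape[1] and not keep.any():
        raise ValueError("no marker has calls in every population")
    n_dropped = int((~keep).sum())
    return freq[:, keep], table.populations, n_dropped


def ward_tree(freq_table: np.ndarray, labels: list[str]) -> PopulationTree:
    """Agglomerative Ward clustering of the rows of ``freq_table``.

    Squared Euclidean distances updated by the Lance-Williams recurrence;
    the pair with the minimal Ward criterion merges first, ties broken by
    the lexicographically smallest pair of sorted member-label tuples.
    Node heights are sqrt of the Ward squared distance (scipy convention).
    """
    freq = np.asarray(freq_table, dtype=float)
    if not np.isfinite(freq).all():
        raise ValueError("non-finite frequencies")
    if freq.shape[0] != len(labels):
        raise ValueError("label count must match rows")
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")

    # active clusters: key -> (node, size, sorted member labels)
    nodes: dict[int, TreeNode] = {i: TreeNode(label=lab) for i, lab in enumerate(labels)}
    sizes: dict[int, int] = {i: 1 for i in nodes}
    members: dict[int, tuple[str, ...]] = {i: (lab,) for i, lab in enumerate(labels)}
    # squared Euclidean distances between active clusters
    d2: dict[frozenset[int], float] = {}
    keys = list(nodes)
    for ai in range(len(keys)):
        for bi in range(ai + 1, len(keys)):
            diff = freq[keys[ai]] - freq[keys[bi]]
            d2[frozenset((keys[ai], keys[bi]))] = float(diff @ diff)
    next_key = len(labels)

    while len(nodes) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...], int, int] | None = None
        for pair, dist in d2.items():
            i, j = sorted(pair)
            mi, mj = sorted((members[i], members[j]))
            cand = (dist, mi, mj, i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        dist, _, _, i, j = best
        height = float(np.sqrt(dist))
        merged = TreeNode(height=height, children=(nodes[i], nodes[j]))
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[frozenset((i, k))]
            djk = d2[frozenset((j, k))]
            dij = dist
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            d2[frozenset((next_key, k))] = new
        for pair in [p for p in d2 if i in p or j in p]:
            del d2[pair]
        members[next_key] = tuple(sorted(members[i] + members[j]))
        del nodes[i], nodes[j], sizes[i], sizes[j], members[i], members[j]
        nodes[next_key] = merged
        sizes[next_key] = ni + nj
        next_key += 1

    (root,) = nodes.values()
    return PopulationTree(root=root, populations=list(labels))


def bootstrap_support(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    n_boot: int = 10000,
    seed: int | None = None,
) -> PopulationTree:
    """Ward tree with clade supports from marker bootstrap.

    Markers are resampled with replacement ``n_boot`` times; the support of
    an internal node is the percentage of replicate trees containing the
    same leaf set.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    freq, labels, _ = frequency_matrix(gm, partition)
    tree = ward_tree(freq, labels)
    counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    L = freq.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        rep = ward_tree(freq[:, idx], labels)
        for clade in rep.clades():
            if clade in counts:
                counts[clade] += 1

    def _assign(node: TreeNode) -> None:
        if node.is_leaf:
            return
        node.support = 100.0 * counts[node.leaves()] / n_boot
        for ch in node.children:
            _assign(ch)

    _assign(tree.root)
    tree.n_bootstrap = n_boot
    return tree
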