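"""Average-linkage clustering of style distance matrices and tree comparison.

The clustering is unweighted average linkage (UPGMA): at each step the two
clusters with the smallest mean pairwise inter-cluster distance are merged,
and the merge height is that mean. Ties are broken by the lexicographically
smallest pair of cluster label tuples, so the merge sequence is a pure
function of the input matrix. Average linkage cannot produce height
inversions, so the resulting tree is ultrametric.

scipy provides the same linkage; it is used in the test suite as an
independent cross-check, not here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrices import PairMatrix, condensed_upper
from .records import StyleSet

Cluster = tuple[str, ...]


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters ``a`` and ``b`` join at ``height``."""

    a: Cluster
    b: Cluster
    height: float

    @property
    def members(self) -> Cluster:
        return tuple(sorted(self.a + self.b))


@dataclass(frozen=True)
class LinkageTree:
    """Rooted ultrametric merge tree over a style roster.

    ``merges`` lists |S| - 1 agglomerations in execution order with
    nondecreasing heights; leaves sit at height 0.
    """

    leaves: StyleSet
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        heights = [m.height for m in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")
        if self.merges and set(self.merges[-1].members) != set(self.leaves.labels):
            raise ValueError("final merge must contain every leaf")

    @property
    def height(self) -> float:
        return self.merges[-1].height if self.merges else 0.0

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes, including the root."""
        return {frozenset(m.members) for m in self.merges}

    def nontrivial_bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Unrooted splits {A | S\\A} with both sides of size >= 2."""
        full = set(self.leaves.labels)
        out: set[frozenset[frozenset[str]]] = set()
        for m in self.merges:
            side = frozenset(m.members)
            other = frozenset(full - side)
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset({side, other}))
        return out


def _mean_intercluster(dist: np.ndarray, idx: dict[str, int], a: Cluster, b: Cluster) -> float:
    """Unweighted mean of all leaf-pair distances between two clusters."""
    total = 0.0
    for la in a:
        ia = idx[la]
        for lb in b:
            total += dist[ia, idx[lb]]
    return total / (len(a) * len(b))


def average_linkage(distance: PairMatrix, *, weighted: bool = False) -> LinkageTree:
    """Agglomerative average-linkage clustering of a style distance matrix.

    Parameters
    ----------
    distance
        Symmetric, zero-diagonal, finite PairMatrix. Missing (NaN) cells or
        asymmetric input raise ValueError naming the offending pair.
    weighted
        If True use WPGMA (the new cluster's distance to others is the plain
        mean of its two parents' distances) instead of the default unweighted
        UPGMA.
    """
    styles = distance.styles
    d = np.asarray(distance.values, dtype=float)
    n = len(styles)
    labels = styles.labels
    for i, j in itertools.combinations(range(n), 2):
        if np.isnan(d[i, j]) or np.isnan(d[j, i]):
            raise ValueError(f"missing distance for pair ({labels[i]}, {labels[j]})")
        if not np.isfinite(d[i, j]) or not np.isfinite(d[j, i]):
            raise ValueError(f"non-finite distance for pair ({labels[i]}, {labels[j]})")
        if abs(d[i, j] - d[j, i]) > 1e-12:
            raise ValueError(
                f"asymmetric input at ({labels[i]}, {labels[j]}): "
                f"{d[i, j]} vs {d[j, i]}; symmetrize first"
            )
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("diagonal must be zero")
    if np.any(d < -1e-12):
        raise ValueError("distances must be nonnegative")

    idx = {lab: i for i, lab in enumerate(labels)}
    active: list[Cluster] = [(lab,) for lab in labels]
    # WPGMA keeps a running cluster-to-cluster distance table.
    wdist: dict[frozenset[Cluster], float] = {}
    if weighted:
        for a, b in itertools.combinations(active, 2):
            wdist[frozenset((a, b))] = _mean_intercluster(d, idx, a, b)

    merges: list[Merge] = []
    while len(active) > 1:
        best: tuple[float, Cluster, Cluster] | None = None
        for a, b in itertools.combinations(sorted(active), 2):
            dd = wdist[frozenset((a, b))] if weighted else _mean_intercluster(d, idx, a, b)
            if best is None or dd < best[0] - 1e-15:
                best = (dd, a, b)
            # ties resolved by the sorted-pair iteration order above
        assert best is not None
        h, a, b = best
        new = tuple(sorted(a + b))
        if weighted:
            for c in active:
                if c is a or c is b or c == a or c == b:
                    continue
                wdist[frozenset((new, c))] = 0.5 * (
                    wdist[frozenset((a, c))] + wdist[frozenset((b, c))]
                )
        active = [c for c in active if c != a and c != b] + [new]
        merges.append(Merge(a=a, b=b, height=float(h)))
    return LinkageTree(leaves=styles, merges=tuple(merges))


def cophenetic(tree: LinkageTree) -> PairMatrix:
    """Cophenetic distances: cell (i, j) is the height of the lowest merge joining i and j."""
    styles = tree.leaves
    n = len(styles)
    values = np.zeros((n, n))
    # each merge joins two disjoint leaf sets, fixing the height for exactly
    # the leaf pairs that straddle it
    for m in tree.merges:
        for la in m.a:
            for lb in m.b:
                i, j = styles.index(la), styles.index(lb)
                values[i, j] = values[j, i] = m.height
    return PairMatrix(styles=styles, values=values, statistic="distance")


def compare_trees(t1: LinkageTree, t2: LinkageTree) -> tuple[int, float]:
    """Topology distance and cophenetic correlation between two trees.

    Returns ``(topology_distance, cophenetic_correlation)`` where the
    topology distance is the number of non-trivial leaf bipartitions present
    in exactly one tree (Robinson–Foulds symmetric difference) and the
    correlation is the Pearson r between the upper triangles of the two
    cophenetic matrices. Only the topology distance is invariant to monotone
    rescaling of heights.
    """
    if set(t1.leaves.labels) != set(t2.leaves.labels):
        only1 = sorted(set(t1.leaves.labels) - set(t2.leaves.labels))
        only2 = sorted(set(t2.leaves.labels) - set(t1.leaves.labels))
        raise ValueError(f"leaf sets differ: only in first {only1}, only in second {only2}")
    b1, b2 = t1.nontrivial_bipartitions(), t2.nontrivial_bipartitions()
    topo = len(b1 ^ b2)

    c1 = cophenetic(t1)
    # align t2's matrix to t1's label order
    order = [t2.leaves.index(lab) for lab in t1.leaves.labels]
    c2v = cophenetic(t2).values[np.ix_(order, order)]
    u1, u2 = condensed_upper(c1.values), condensed_upper(c2v)
    if np.std(u1) == 0 or np.std(u2) == 0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(u1, u2).statistic)
    return topo, corr


# ---------------------------------------------------------------------------
# newick import/export


def to_newick(tree: LinkageTree) -> str:
    """Serialize as newick; branch lengths are height differences, leaves at 0."""
    node_height: dict[Cluster, float] = {(lab,): 0.0 for lab in tree.leaves.labels}
    node_text: dict[Cluster, str] = {(lab,): lab for lab in tree.leaves.labels}
    for m in tree.merges:
        la = m.height - node_height[m.a]
        lb = m.height - node_height[m.b]
        text = f"({node_text[m.a]}:{la:.10g},{node_text[m.b]}:{lb:.10g})"
        node_text[m.members] = text
        node_height[m.members] = m.height
    root = tree.merges[-1].members if tree.merges else (tree.leaves.labels[0],)
    return node_text[root] + ";"


def from_newick(text: str, styles: StyleSet | None = None) -> LinkageTree:
    """Parse a newick string into a LinkageTree.

    The tree must be ultrametric (all leaves equidistant from the root, up to
    1e-6 relative): the leaf-pair patristic distances are halved to recover
    cophenetic heights and average linkage on that ultrametric matrix rebuilds
    the merge list exactly.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    taxa = sorted(leaf.taxon.label for leaf in dtree.leaf_node_iter())
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate leaf labels in newick")
    if styles is None:
        styles = StyleSet(tuple(taxa))
    elif set(styles.labels) != set(taxa):
        raise ValueError(f"newick leaves {taxa} do not match roster {styles.labels}")

    pdm = dtree.phylogenetic_distance_matrix()
    n = len(styles)
    values = np.zeros((n, n))
    taxon_by_label = {t.label: t for t in dtree.taxon_namespace}
    for i, j in itertools.combinations(range(n), 2):
        pat = pdm.patristic_distance(
            taxon_by_label[styles.labels[i]], taxon_by_label[styles.labels[j]]
        )
        values[i, j] = values[j, i] = pat / 2.0
    # ultrametricity check: d(i,k) <= max(d(i,j), d(j,k)) for all triples
    scale = values.max() or 1.0
    for i, j, k in itertools.combinations(range(n), 3):
        trio = sorted([values[i, j], values[i, k], values[j, k]])
        if trio[2] - trio[1] > 1e-6 * scale:
            raise ValueError(
                "newick tree is not ultrametric; cannot interpret as a merge tree"
            )
    dm = PairMatrix(styles=styles, values=values, statistic="distance")
    return average_linkage(dm)


def reference_taxonomy() -> LinkageTree:
    """The art-historical reference clustering of the eight styles.

    Topology transcribed from the study's narrative account: the two phases
    of Impressionism (EI, LI) cluster, as do the two phases of Expressionism
    (EE, LE), with within-era similarity exceeding across-era similarity;
    Gauguin sits closer to Cézanne than van Gogh does, with van Gogh joining
    the Cézanne–Gauguin pair; photography is the outgroup. Merge heights are
    arbitrary ordinal placeholders — only the topology is meaningful for
    comparison.
    """
    newick = (
        "((((EI:1,LI:1):1,(EE:1,LE:1):1):1,((C:1,G:1):1,VG:2):1):1,P:4);"
    )
    return from_newick(newick)
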