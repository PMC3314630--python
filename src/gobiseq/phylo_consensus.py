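"""Bipartition-consensus phylogeny via a 0/1 split matrix and BioNJ.

The consensus procedure takes a collection of support-annotated gene trees
and builds a species phylogeny in four steps:

1. extract every non-trivial bipartition (split) whose bootstrap support
   reaches a threshold (default 70%, inclusive);
2. encode all recorded splits as a taxa x splits 0/1 matrix (duplicate
   splits from different trees are kept as separate columns, so frequent
   splits weigh more; taxa absent from a source tree are coded missing);
3. compute pairwise p-distances (normalised Hamming distance over columns
   where both taxa are defined);
4. build the tree with BioNJ (Gascuel 1997): neighbor joining with
   variance-weighted reduction, where the update weight lambda minimises
   the variance of the new distance estimates.

The BioNJ agglomeration is implemented here; dendropy provides the tree
container, Newick I/O and (in the test-suite) the Robinson-Foulds oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

MISSING = -1  # matrix code for "taxon absent from the source tree"


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of a tree's leaf set.

    ``side`` is the half not containing the lexicographically smallest leaf
    of the source tree (a canonical choice, so equal splits compare equal);
    ``leaf_set`` is the full leaf set of the source tree.
    """

    side: frozenset[str]
    leaf_set: frozenset[str]

    def __post_init__(self) -> None:
        other = self.leaf_set - self.side
        if len(self.side) < 2 or len(other) < 2:
            raise ValueError("trivial bipartition")

    @property
    def other_side(self) -> frozenset[str]:
        return self.leaf_set - self.side


@dataclass
class BipartitionMatrix:
    """Taxa x splits character matrix with states 0/1/missing."""

    taxa: tuple[str, ...]
    data: np.ndarray  # int8, shape (n_taxa, n_cols), MISSING = -1
    provenance: list[tuple[int, Bipartition]] = field(default_factory=list)


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v


def parse_newick_support(text: str) -> dendropy.Tree:
    """Parse a Newick string whose internal-node labels are supports.

    Raises on duplicate leaf names (dendropy rejects re-used taxon labels).
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf names in Newick input")
    return tree


def _node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def tree_bipartitions(tree: dendropy.Tree) -> dict[Bipartition, float | None]:
    """All non-trivial splits of a tree with their supports.

    The two root-child edges of a rooted binary tree induce the same split;
    duplicates keep the larger support.
    """
    leaf_set = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(leaf_set)
    out: dict[Bipartition, float | None] = {}
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = leaf_set - below if anchor in below else below
        if len(side) < 2 or len(leaf_set - side) < 2:
            continue
        bp = Bipartition(side=side, leaf_set=leaf_set)
        sup = _node_support(node)
        if bp in out:
            prev = out[bp]
            if prev is None or (sup is not None and sup > prev):
                out[bp] = sup
        else:
            out[bp] = sup
    return out


def extract_bipartitions(
    tree: dendropy.Tree, min_support: float = 70.0
) -> set[Bipartition]:
    """Non-trivial splits with support >= ``min_support`` (inclusive).

    Splits without a support value are not extracted unless
    ``min_support`` <= 0.
    """
    out = set()
    for bp, sup in tree_bipartitions(tree).items():
        if sup is None:
            if min_support <= 0:
                out.add(bp)
        elif sup >= min_support:
            out.add(bp)
    return out


def encode_matrix(
    split_sets: Sequence[Iterable[Bipartition]],
    taxon_universe: Iterable[str],
) -> BipartitionMatrix:
    """Encode recorded splits, one column per split occurrence.

    The side containing the lexicographically smallest defined taxon is
    coded 0, the other side 1; taxa absent from the source tree are coded
    missing.  Duplicate splits across trees stay as separate columns.
    """
    taxa = tuple(sorted(set(taxon_universe)))
    index = {t: i for i, t in enumerate(taxa)}
    cols: list[np.ndarray] = []
    provenance: list[tuple[int, Bipartition]] = []
    for tree_idx, splits in enumerate(split_sets):
        for bp in sorted(splits, key=lambda b: (sorted(b.side), sorted(b.leaf_set))):
            col = np.full(len(taxa), MISSING, dtype=np.int8)
            defined = sorted(bp.leaf_set & set(taxa))
            if not defined:
                continue
            zero_side = bp.side if defined[0] in bp.side else bp.other_side
            one_side = bp.leaf_set - zero_side
            for t in zero_side:
                if t in index:
                    col[index[t]] = 0
            for t in one_side:
                if t in index:
                    col[index[t]] = 1
            if (col == 0).any() and (col == 1).any():
                cols.append(col)
                provenance.append((tree_idx, bp))
    if not cols:
        raise ValueError("no splits to encode")
    return BipartitionMatrix(
        taxa=taxa, data=np.column_stack(cols), provenance=provenance
    )


def p_distance(matrix: BipartitionMatrix) -> DistanceMatrix:
    """Normalised Hamming distance over mutually defined columns.

    d(i,j) = (#columns where both defined and states differ) /
    (#columns where both defined).  A pair sharing no defined column is an
    error (the taxa are named).
    """
    data = matrix.data
    n = len(matrix.taxa)
    d = np.zeros((n, n))
    defined = data != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = defined[i] & defined[j]
            shared = int(both.sum())
            if shared == 0:
                raise ValueError(
                    f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no "
                    "defined columns"
                )
            diff = int((data[i, both] != data[j, both]).sum())
            d[i, j] = d[j, i] = diff / shared
    return DistanceMatrix(taxa=matrix.taxa, values=d)


def bionj(d: DistanceMatrix, clamp_negative: bool = False) -> dendropy.Tree:
    """BioNJ agglomerative tree construction (Gascuel 1997).

    Pairs are chosen by the neighbor-joining Q criterion; branch lengths by
    the standard NJ formulas; the reduction uses the variance-weighted
    update d(u,k) = lam*(d(i,k)-b_i) + (1-lam)*(d(j,k)-b_j) with variances
    initialised to the distances, v(u,k) = lam*v(i,k) + (1-lam)*v(j,k)
    - lam*(1-lam)*v(i,j), and lam = 1/2 + sum_k(v(j,k)-v(i,k)) /
    (2*(r-2)*v(i,j)) clamped to [0,1] (1/2 when v(i,j)=0).  Q ties break
    on the lexicographically smallest taxon pair.  Negative branch lengths
    are reported as computed unless ``clamp_negative``.

    Returns an unrooted tree (trifurcation at the seed node).
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("BioNJ needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(d.taxa))
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in d.taxa]
    labels = list(d.taxa)  # smallest member taxon of each cluster, for ties
    D = d.values.astype(float).copy()
    V = D.copy()

    def _blen(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((labels[i], labels[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        b_i = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        b_j = dij - b_i
        denom = 2 * (m - 2) * V[i, j]
        if denom > 0:
            others = [k for k in range(m) if k != i and k != j]
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / denom
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _blen(b_i)
        parent.add_child(nodes[j])
        nodes[j].edge.length = _blen(b_j)

        keep = [k for k in range(m) if k != i and k != j]
        new_d = np.empty(len(keep))
        new_v = np.empty(len(keep))
        for idx, k in enumerate(keep):
            new_d[idx] = lam * (D[i, k] - b_i) + (1 - lam) * (D[j, k] - b_j)
            new_v[idx] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * V[i, j]
        D = D[np.ix_(keep, keep)]
        V = V[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = new_d
        V[-1, :-1] = V[:-1, -1] = new_v
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # final three clusters joined at an unrooted trifurcation
    (x, y, z) = (0, 1, 2)
    b_x = (D[x, y] + D[x, z] - D[y, z]) / 2
    b_y = (D[x, y] + D[y, z] - D[x, z]) / 2
    b_z = (D[x, z] + D[y, z] - D[x, y]) / 2
    root = dendropy.Node()
    for node, b in zip(nodes, (b_x, b_y, b_z)):
        root.add_child(node)
        node.edge.length = _blen(b)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def consensus_pipeline(
    gene_trees: Sequence[dendropy.Tree | str],
    min_support: float = 70.0,
) -> dendropy.Tree:
    """Extract -> encode -> p-distance -> BioNJ, over the union of taxa."""
    trees = [
        t if isinstance(t, dendropy.Tree) else parse_newick_support(t)
        for t in gene_trees
    ]
    if not trees:
        raise ValueError("no gene trees supplied")
    universe: set[str] = set()
    for t in trees:
        universe |= {lf.taxon.label for lf in t.leaf_node_iter()}
    if len(universe) < 3:
        raise ValueError("gene trees share fewer than 3 taxa")
    split_sets = [extract_bipartitions(t, min_support) for t in trees]
    matrix = encode_matrix(split_sets, universe)
    return bionj(p_distance(matrix))


def write_phylip_01(matrix: BipartitionMatrix, path) -> None:
    """Relaxed PHYLIP-style 0/1 characters with '?' for missing."""
    symbols = {0: "0", 1: "1", MISSING: "?"}
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.data.shape[1]}\n")
        for i, t in enumerate(matrix.taxa):
            chars = "".join(symbols[int(v)] for v in matrix.data[i])
            fh.write(f"{t}\t{chars}\n")


def write_distance_tsv(d: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(d.taxa) + "\n")
        for i, t in enumerate(d.taxa):
            fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in d.values[i]) + "\n")


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted RF distance via shared-namespace split comparison."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)
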