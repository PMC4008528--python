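"""Distance-based cladograms with bootstrap support and clade assignment.

Trees are built by neighbor joining (Saitou-Nei) on pairwise p-distances -
an explicit substitution for the progressive-alignment guide trees behind
the original similarity cladograms; UPGMA is available as an alternative
agglomeration. Bipartition support comes from column-resampling bootstrap
replicates. The two survey clades are assigned as the smallest monophyletic
groups containing user-supplied anchor leaves after rooting between the
anchor sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diversity import pairwise_p_distance
from .genome_io import Msa


@dataclass
class LabeledTree:
    """A phylogeny with optional per-leaf clade / overlap-type annotations
    and per-bipartition bootstrap supports (percent, internal edges)."""

    tree: dendropy.Tree
    clade: dict[str, str] = field(default_factory=dict)
    overlap_type: dict[str, str] = field(default_factory=dict)
    supports: dict[int, float] = field(default_factory=dict)  # split bitmask -> %

    @property
    def taxon_namespace(self) -> dendropy.TaxonNamespace:
        return self.tree.taxon_namespace

    def leaf_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def distance_matrix(msa: Msa) -> tuple[list[str], np.ndarray]:
    """Symmetric pairwise p-distance matrix of an alignment."""
    if msa.n_rows < 3:
        raise ValueError("need at least 3 sequences")
    n = msa.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_p_distance(msa.rows[i], msa.rows[j])
            if d is None:
                raise ValueError(
                    f"no comparable sites between {msa.names[i]!r} and {msa.names[j]!r}")
            D[i, j] = D[j, i] = d
    return list(msa.names), D


def neighbor_joining(D: np.ndarray, names: list[str],
                     taxon_namespace: dendropy.TaxonNamespace | None = None,
                     ) -> LabeledTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q-matrix break on the smallest (i, j) index pair; negative
    branch lengths are clamped to zero with the excess moved to the sister
    branch. Returns an unrooted tree (trifurcating seed node).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(names)
    nodes: list[dendropy.Node] = []
    for name in names:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    active = list(range(n))
    dist = D.copy()

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: first minimum = smallest (i, j)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dij)
        dist = np.vstack([dist, new_row])
        new_col = np.append(new_row, 0.0)
        dist = np.column_stack([dist, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final three-point join
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return LabeledTree(tree=tree)


def upgma(D: np.ndarray, names: list[str]) -> LabeledTree:
    """UPGMA agglomeration (alternative to neighbor joining)."""
    import scipy.cluster.hierarchy as sch
    from scipy.spatial.distance import squareform
    Z = sch.linkage(squareform(np.asarray(D, dtype=float), checks=False),
                    method="average")
    tns = dendropy.TaxonNamespace(names)
    nodes = [dendropy.Node(taxon=tns.get_taxon(nm)) for nm in names]
    heights = [0.0] * len(names)
    for a, b, h, _cnt in Z:
        pa = dendropy.Node()
        for child in (int(a), int(b)):
            pa.add_child(nodes[child])
            nodes[child].edge.length = h / 2.0 - heights[child]
        nodes.append(pa)
        heights.append(h / 2.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[-1])
    tree.is_rooted = True
    return LabeledTree(tree=tree)


def _bipartition_masks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    masks = set()
    n_tax = len(tree.taxon_namespace)
    full = (1 << n_tax) - 1
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node.is_leaf():
            continue
        mask = int(edge.bipartition.split_bitmask)
        if mask in (0, full):
            continue
        masks.add(mask)
    return masks


def bootstrap_support(msa: Msa, n_reps: int = 1000, seed: int = 0,
                      method: str = "nj") -> LabeledTree:
    """NJ tree of the full alignment with column-bootstrap supports.

    Support is the percentage of replicates whose tree contains each
    internal bipartition of the base tree."""
    if msa.n_rows < 4:
        raise ValueError("need at least 4 taxa for bootstrap supports")
    names, D = distance_matrix(msa)
    build = neighbor_joining if method == "nj" else (lambda d, n, **kw: upgma(d, n))
    base = build(D, names)
    base_masks = _bipartition_masks(base.tree)
    counts = {m: 0 for m in base_masks}
    rng = np.random.default_rng(seed)
    L = msa.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[c] for c in cols) for r in msa.rows]
        rep = Msa(names=list(msa.names), rows=rows)
        try:
            _, Dr = distance_matrix(rep)
        except ValueError:
            continue
        rep_tree = build(Dr, names, taxon_namespace=base.taxon_namespace) \
            if method == "nj" else build(Dr, names)
        if method != "nj":
            rep_tree.tree.migrate_taxon_namespace(base.taxon_namespace)
        rep_masks = _bipartition_masks(rep_tree.tree)
        for m in base_masks:
            if m in rep_masks:
                counts[m] += 1
    base.supports = {m: 100.0 * c / n_reps for m, c in counts.items()}
    # annotate internal node labels with rounded support
    base.tree.encode_bipartitions()
    for node in base.tree.preorder_node_iter():
        if node.is_leaf() or node.edge.bipartition is None:
            continue
        mask = int(node.edge.bipartition.split_bitmask)
        if mask in base.supports:
            node.label = f"{base.supports[mask]:.0f}"
    return base


def split_support(tree: LabeledTree, leaves: set[str]) -> float | None:
    """Bootstrap support (%) of the bipartition separating ``leaves`` from
    the rest, or None if the base tree lacks that split."""
    tns = tree.taxon_namespace
    mask = 0
    for taxon in tns:
        if taxon.label in leaves:
            mask |= int(tns.taxon_bitmask(taxon))
    full = (1 << len(tns)) - 1
    for m, s in tree.supports.items():
        if m == mask or m == (full ^ mask):
            return s
    return None


def assign_clades(tree: LabeledTree, anchors: dict[str, str]) -> LabeledTree:
    """Assign each leaf to the smallest monophyletic group containing all
    anchors of its clade.

    On the unrooted tree every edge defines two clans (bipartition sides);
    a clade is the smallest clan containing all of its anchors and no
    anchor of the other clade - equivalent to taking MRCAs after rooting
    between the two anchor sets. ``anchors`` maps leaf label -> clade
    label (>= 1 anchor per clade). Leaves in neither group become
    'unassigned'; anchors that no edge separates are an error."""
    labels = set(tree.leaf_labels())
    for leaf in anchors:
        if leaf not in labels:
            raise ValueError(f"anchor {leaf!r} not in tree")
    clades = sorted(set(anchors.values()))
    if len(clades) != 2:
        raise ValueError("need anchors for exactly two clades")
    by_clade = {c: {l for l, cl in anchors.items() if cl == c} for c in clades}

    t = tree.tree
    t.encode_bipartitions()
    tns = t.taxon_namespace
    bit_of = {taxon.label: int(tns.taxon_bitmask(taxon)) for taxon in tns}
    full = (1 << len(tns)) - 1
    anchor_mask = {c: sum(bit_of[l] for l in by_clade[c]) for c in clades}

    sides = {full}  # the whole leaf set is always a candidate clan
    for edge in t.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        m = int(edge.bipartition.split_bitmask)
        if m not in (0, full):
            sides.update({m, full ^ m})

    chosen: dict[str, int] = {}
    for c in clades:
        other = [x for x in clades if x != c][0]
        ok = [m for m in sides
              if (m & anchor_mask[c]) == anchor_mask[c] and not (m & anchor_mask[other])]
        if not ok:
            raise ValueError("clades not monophyletic: anchors not separable")
        chosen[c] = min(ok, key=lambda m: bin(m).count("1"))
    if chosen[clades[0]] & chosen[clades[1]]:
        raise ValueError("clades not monophyletic: anchor groups overlap")

    assignment: dict[str, str] = {}
    for label in labels:
        bit = bit_of[label]
        for c in clades:
            if chosen[c] & bit:
                assignment[label] = c
    tree.clade = {label: assignment.get(label, "unassigned") for label in labels}
    return tree
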