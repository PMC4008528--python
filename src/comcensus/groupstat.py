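"""Trait-phylogeny association tests for overlap types.

Two permutation tests ask whether the reading-frame overlap types of the
loci segregate with sequence phylogeny rather than being scattered at
random:

* P-test: the minimum number of state changes (parsimony, Fitch/Hartigan)
  needed to explain the leaf trait states on the tree, compared with the
  change counts after shuffling the states across leaves; small observed
  counts indicate phylogenetic clustering of the trait.
* F-test (Martin-style): an FST-like statistic
  ``F = (theta_T - theta_W) / theta_T`` where theta_T is the mean pairwise
  sequence distance over all pairs and theta_W the mean over within-group
  pairs pooled across groups; significance by permuting group labels.

Both p-values use the add-one convention ``(1 + #extreme) / (n_perm + 1)``
and are therefore never exactly zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .phylo import LabeledTree


@dataclass
class PTestResult:
    observed_changes: int
    null_distribution: np.ndarray
    p: float
    n_perm: int
    seed: int


@dataclass
class FTestResult:
    F: float
    theta_T: float
    theta_W: float
    null_distribution: np.ndarray
    p: float
    n_perm: int
    seed: int


def _as_tree(tree: "LabeledTree | dendropy.Tree") -> dendropy.Tree:
    return tree.tree if isinstance(tree, LabeledTree) else tree


def _tree_structure(tree: dendropy.Tree) -> tuple[list[list[int]], dict[str, int]]:
    """Postorder child-index lists; leaves come first (index = leaf order)."""
    leaves = [n for n in tree.leaf_node_iter()]
    leaf_index = {id(n): i for i, n in enumerate(leaves)}
    label_index = {n.taxon.label: i for i, n in enumerate(leaves)}
    children: list[list[int]] = [[] for _ in leaves]
    node_index: dict[int, int] = dict(leaf_index)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        idx = len(children)
        node_index[id(node)] = idx
        children.append([node_index[id(c)] for c in node.child_nodes()])
    return children, label_index


def _hartigan_changes(children: list[list[int]], n_leaves: int,
                      leaf_state_sets: list[int]) -> int:
    """Minimum state changes on the tree (Hartigan's generalization of
    Fitch to arbitrary arity), with state sets as bitmasks."""
    sets = leaf_state_sets + [0] * (len(children) - n_leaves)
    changes = 0
    for idx in range(n_leaves, len(children)):
        counts: dict[int, int] = {}
        for ch in children[idx]:
            mask = sets[ch]
            bit = 1
            while mask:
                if mask & 1:
                    counts[bit] = counts.get(bit, 0) + 1
                mask >>= 1
                bit <<= 1
        best = max(counts.values())
        union = 0
        for bit, cnt in counts.items():
            if cnt == best:
                union |= bit
        sets[idx] = union
        changes += len(children[idx]) - best
    return changes


def fitch_changes(tree: "LabeledTree | dendropy.Tree",
                  leaf_states: dict[str, str]) -> int:
    """Minimum number of categorical state changes on the tree.

    Every leaf must carry a state; works on binary and multifurcating
    trees (exact minimum via Hartigan's bottom-up pass)."""
    t = _as_tree(tree)
    children, label_index = _tree_structure(t)
    n_leaves = len(label_index)
    states = sorted(set(leaf_states.values()))
    state_bit = {s: 1 << i for i, s in enumerate(states)}
    leaf_sets = [0] * n_leaves
    for label, idx in label_index.items():
        if label not in leaf_states:
            raise ValueError(f"leaf {label!r} has no state")
        leaf_sets[idx] = state_bit[leaf_states[label]]
    return _hartigan_changes(children, n_leaves, leaf_sets)


def _random_topology(n_leaves: int, rng: np.random.Generator) -> list[list[int]]:
    """Random binary topology over ``n_leaves`` (random sequential joins),
    as postorder child-index lists compatible with the Hartigan pass."""
    children: list[list[int]] = [[] for _ in range(n_leaves)]
    active = list(range(n_leaves))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        children.append([active[i], active[j]])
        active = [v for k, v in enumerate(active) if k not in (i, j)]
        active.append(len(children) - 1)
    return children


def p_test(tree: "LabeledTree | dendropy.Tree", leaf_states: dict[str, str],
           n_perm: int = 1000, seed: int = 0, null: str = "labels") -> PTestResult:
    """Parsimony P-test: are trait states phylogenetically clustered?

    ``null='labels'`` (default) shuffles states across leaves of the fixed
    tree - the exchangeability null; ``null='random_tree'`` instead regrows
    a random topology per replicate with the observed states, for
    sensitivity analysis. p = (1 + #{null <= observed}) / (n_perm + 1)."""
    if null not in ("labels", "random_tree"):
        raise ValueError("null must be 'labels' or 'random_tree'")
    t = _as_tree(tree)
    children, label_index = _tree_structure(t)
    n_leaves = len(label_index)
    labels = sorted(label_index, key=label_index.get)
    states = sorted(set(leaf_states.values()))
    if len(states) < 2:
        warnings.warn("single trait state: P-test is degenerate, p = 1")
        return PTestResult(observed_changes=0,
                           null_distribution=np.zeros(0), p=1.0,
                           n_perm=n_perm, seed=seed)
    state_bit = {s: 1 << i for i, s in enumerate(states)}
    obs_sets = [state_bit[leaf_states[l]] for l in labels]
    observed = _hartigan_changes(children, n_leaves, list(obs_sets))
    rng = np.random.default_rng(seed)
    null_dist = np.empty(n_perm, dtype=int)
    arr = np.array(obs_sets)
    for b in range(n_perm):
        if null == "labels":
            null_dist[b] = _hartigan_changes(children, n_leaves,
                                             rng.permutation(arr).tolist())
        else:
            topo = _random_topology(n_leaves, rng)
            null_dist[b] = _hartigan_changes(topo, n_leaves, list(obs_sets))
    p = (1.0 + np.sum(null_dist <= observed)) / (n_perm + 1.0)
    return PTestResult(observed_changes=observed, null_distribution=null_dist,
                       p=float(p), n_perm=n_perm, seed=seed)


def f_statistic(D: np.ndarray, group_ids: np.ndarray) -> tuple[float, float, float]:
    """(F, theta_T, theta_W); within-group pairs pooled across groups,
    groups with < 2 members contribute nothing to theta_W."""
    n = D.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vals = D[ii, jj]
    theta_T = float(vals.mean())
    within = group_ids[ii] == group_ids[jj]
    if not np.any(within):
        raise ValueError("no group has >= 2 members")
    theta_W = float(vals[within].mean())
    if theta_T == 0:
        return 0.0, theta_T, theta_W
    return (theta_T - theta_W) / theta_T, theta_T, theta_W


def f_test(D: np.ndarray, names: list[str], groups: dict[str, str],
           n_perm: int = 10000, seed: int = 0) -> FTestResult:
    """Permutation F-test of group differentiation on a distance matrix.

    ``groups`` maps sequence name -> group label; groups with fewer than
    two members are excluded from theta_W (with a warning). Null F values
    come from shuffling group labels; p = (1 + #{F_null >= F}) / (n_perm + 1).
    """
    D = np.asarray(D, dtype=float)
    group_labels = [groups[n] for n in names]
    sizes: dict[str, int] = {}
    for g in group_labels:
        sizes[g] = sizes.get(g, 0) + 1
    small = {g for g, c in sizes.items() if c < 2}
    if small:
        warnings.warn(f"groups with < 2 members excluded from theta_W: {sorted(small)}")
    if len([g for g in sizes if g not in small]) < 1:
        raise ValueError("every group has < 2 members")
    uniq = sorted(sizes)
    gid = np.array([uniq.index(g) for g in group_labels])
    # single-member groups get unique negative ids: never form within pairs
    neg = -1
    for g in small:
        gid[gid == uniq.index(g)] = neg
        neg -= 1
    F, theta_T, theta_W = f_statistic(D, gid)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(gid)
        null[b], _, _ = f_statistic(D, perm)
    p = (1.0 + np.sum(null >= F)) / (n_perm + 1.0)
    return FTestResult(F=float(F), theta_T=theta_T, theta_W=theta_W,
                       null_distribution=null, p=float(p), n_perm=n_perm,
                       seed=seed)
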