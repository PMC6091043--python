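"""Tree I/O and manipulation utilities.

Trees are :class:`dendropy.Tree` objects throughout the package. This
module wraps reading/writing (newick single trees, nexus tree sets with
TRANSLATE blocks) and provides the manipulations the comparative
analysis needs: collapsing poorly supported edges to polytomies,
uniform random resolution of polytomies, height rescaling, patristic
distance / phylogenetic covariance matrices, and trait–tree alignment.

Conventions
-----------
* Support values live on internal-node labels (newick internal-label
  convention); they are attached to the child node of an edge.
* Collapsing an edge adds its length onto the child edges of the
  removed node, so root-to-tip path lengths are preserved.
* Edges inserted by random resolution have length 0.
"""

from __future__ import annotations

import random as _random

import dendropy
import numpy as np

__all__ = [
    "read_newick",
    "write_newick",
    "tree_from_string",
    "tree_to_string",
    "read_nexus_trees",
    "tip_labels",
    "tree_height",
    "is_ultrametric",
    "collapse_low_support",
    "resolve_polytomies_random",
    "rescale_height",
    "vcv",
    "patristic_distances",
    "prune_to_taxa",
    "align_trait",
]


# ---------------------------------------------------------------------------
# I/O

_READ_KW = dict(schema="newick", preserve_underscores=True, rooting="default-rooted")


def read_newick(path) -> dendropy.Tree:
    """Read a single rooted newick tree; underscores in labels are literal."""
    try:
        return dendropy.Tree.get(path=str(path), **_READ_KW)
    except dendropy.utility.error.DataParseError as e:
        raise ValueError(f"malformed newick in {path}: {e}") from e


def tree_from_string(s: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=s, **_READ_KW)
    except dendropy.utility.error.DataParseError as e:
        raise ValueError(f"malformed newick: {e}") from e


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_string(tree) + "\n")


def read_nexus_trees(path) -> list[dendropy.Tree]:
    """Read a nexus tree set (TRANSLATE blocks supported)."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="nexus", preserve_underscores=True,
        rooting="default-rooted",
    )
    return list(trees)


# ---------------------------------------------------------------------------
# basic queries


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    """Distance from the root for every node (root edge length ignored)."""
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    depths = _node_depths(tree)
    return max(depths[lf] for lf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = 1e-6) -> bool:
    """True when all root-to-tip distances agree within ``rtol`` of height."""
    depths = _node_depths(tree)
    tip_depths = np.array([depths[lf] for lf in tree.leaf_node_iter()])
    h = tip_depths.max()
    if h == 0:
        return True
    return bool(np.all(np.abs(tip_depths - h) <= rtol * h))


# ---------------------------------------------------------------------------
# manipulations


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract internal edges whose child node's support is below ``threshold``.

    Support is read from internal-node labels; the root and unlabeled
    nodes are exempt. Contracted edge lengths are absorbed into the
    child edges, preserving tip depths. Returns a modified copy.
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for nd in tree.preorder_internal_node_iter(exclude_seed_node=True):
        if nd.label is None:
            continue
        try:
            support = float(nd.label)
        except ValueError:
            continue
        if support < threshold:
            to_collapse.append(nd)
    for nd in to_collapse:
        parent = nd.parent_node
        elen = nd.edge.length or 0.0
        for ch in list(nd.child_nodes()):
            ch.edge.length = (ch.edge.length or 0.0) + elen
            parent.add_child(ch)
        parent.remove_child(nd)
    return tree


class _Join:
    """Binary join used while building a random resolution."""

    __slots__ = ("left", "right")

    def __init__(self, left, right):
        self.left = left
        self.right = right


def _random_binary_topology(items: list, rng: _random.Random):
    """Uniform rooted binary topology over ``items``.

    Sequential edge insertion: leaf k+1 is attached to one of the 2k-1
    edges (including the root edge) chosen uniformly, which generates
    every rooted labeled topology exactly once — hence uniformly.
    """
    root = _Join(items[0], items[1])
    for item in items[2:]:
        # enumerate attachment points: every subtree, incl. the root
        stack, subtrees = [(None, root)], []
        while stack:
            parent_slot, sub = stack.pop()
            subtrees.append((parent_slot, sub))
            if isinstance(sub, _Join):
                stack.append(((sub, "left"), sub.left))
                stack.append(((sub, "right"), sub.right))
        parent_slot, target = subtrees[rng.randrange(len(subtrees))]
        new = _Join(target, item)
        if parent_slot is None:
            root = new
        else:
            node, side = parent_slot
            setattr(node, side, new)
    return root


def resolve_polytomies_random(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Resolve every polytomy uniformly at random over rooted resolutions.

    Inserted edges get length 0, so tip-to-root path lengths (and
    ultrametricity) are unchanged. Reproducible per seed. Returns a
    modified copy.
    """
    rng = _random.Random(seed)
    tree = tree.clone(depth=1)
    for nd in list(tree.preorder_node_iter()):
        children = nd.child_nodes()
        if len(children) <= 2:
            continue
        topo = _random_binary_topology(children, rng)
        for ch in children:
            nd.remove_child(ch)

        def attach(parent, sub):
            if isinstance(sub, _Join):
                mid = dendropy.Node()
                mid.edge.length = 0.0
                parent.add_child(mid)
                attach(mid, sub.left)
                attach(mid, sub.right)
            else:
                parent.add_child(sub)  # original child keeps its edge length

        attach(nd, topo.left)
        attach(nd, topo.right)
    return tree


def rescale_height(tree: dendropy.Tree, target_height: float) -> dendropy.Tree:
    """Scale all branch lengths so root-to-tip distance equals ``target_height``.

    Requires an ultrametric input (all tips equidistant from the root).
    """
    if not is_ultrametric(tree):
        raise ValueError("rescale_height requires an ultrametric tree")
    h = tree_height(tree)
    if h <= 0:
        raise ValueError("tree has zero height")
    factor = target_height / h
    tree = tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return tree


# ---------------------------------------------------------------------------
# distances


def vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance matrix (shared root-to-MRCA path lengths).

    Returns ``(labels, C)`` where ``C[i, j]`` is the depth of the MRCA
    of tips i and j and the diagonal holds tip depths. Single O(n^2)
    postorder pass.
    """
    labels = tip_labels(tree)
    index = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depths = _node_depths(tree)
    tipsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[nd.taxon.label]
            tipsets[nd] = [i]
            C[i, i] = depths[nd]
        else:
            groups = [tipsets.pop(ch) for ch in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            tipsets[nd] = [i for g in groups for i in g]
    return labels, C


def patristic_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Pairwise tip-to-tip path lengths, via d(i,j) = h_i + h_j - 2 mrca(i,j)."""
    labels, C = vcv(tree)
    h = np.diag(C)
    D = h[:, None] + h[None, :] - 2 * C
    np.fill_diagonal(D, 0.0)
    return labels, D


# ---------------------------------------------------------------------------
# pruning and trait alignment


def prune_to_taxa(tree: dendropy.Tree, names) -> dendropy.Tree:
    """Restrict the tree to ``names``; unifurcations suppressed, lengths summed."""
    names = set(names)
    present = names & set(tip_labels(tree))
    if not present:
        raise ValueError("no overlap between requested names and tree tips")
    return tree.extract_tree_with_taxa_labels(labels=present)


def align_trait(
    tree: dendropy.Tree, trait: dict, on_missing: str = "prune"
) -> tuple[dendropy.Tree, list]:
    """Prune tree and trait to their shared tips and order the trait values.

    ``on_missing`` controls tips lacking a trait value: ``"prune"``
    drops them, ``"error"`` raises. Returns the pruned tree and values
    ordered to match its tip-iteration order.
    """
    tips = set(tip_labels(tree))
    missing = tips - set(trait)
    if missing and on_missing == "error":
        raise KeyError(f"trait missing for tips: {sorted(missing)[:5]} ...")
    keep = tips & set(trait)
    if not keep:
        raise ValueError("no tips with trait values")
    pruned = prune_to_taxa(tree, keep) if missing or keep != tips else tree
    values = [trait[lb] for lb in tip_labels(pruned)]
    return pruned, values
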