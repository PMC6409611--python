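"""Distance phylogenetics and clade-partition-labeled trees.

The tree container used across the package is :class:`LabeledTree`: an
(un)rooted tree whose every branch carries an integer clade-partition label
(0 = background). Labels are serialized in Newick with the ``$k`` suffix
convention — a tag on a node applies to the branch above it and, implicitly,
to its whole subtree until overridden by a deeper tag::

    (a:1,b:2,(c:1,d:1)$1:0.5);

Also here: pairwise distances with pairwise gap deletion (p, Poisson,
Jukes–Cantor), Saitou–Nei neighbor joining with a deterministic tie rule,
and nonparametric bootstrap support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import ProteinAlignment

__all__ = [
    "Node",
    "LabeledTree",
    "DistanceMatrix",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "label_clades",
    "merge_partitions",
    "read_partition_map",
    "path_length_matrix",
]


class Node:
    """Tree node; ``length``, ``partition`` and ``support`` describe the
    branch above the node (all None/default at the root)."""

    __slots__ = ("name", "length", "partition", "support", "children", "parent")

    def __init__(self, name=None, length=None, partition=0, support=None):
        self.name = name
        self.length = length
        self.partition = partition
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LabeledTree:
    """Phylogeny with branch lengths and per-branch clade-partition labels."""

    def __init__(self, root: Node):
        self.root = root
        for node in self.preorder():
            for ch in node.children:
                ch.parent = node
        self.root.parent = None

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def postorder(self) -> list[Node]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def partitions(self) -> set[int]:
        labs = {n.partition for n in self.preorder() if n.parent is not None}
        return labs or {0}

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(name)

    def copy(self) -> "LabeledTree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length, n.partition, n.support)
            for ch in n.children:
                m.add(clone(ch))
            return m

        return LabeledTree(clone(self.root))

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise ValueError(f"malformed Newick: {exc}") from exc

        def strip_tag(label: str | None) -> tuple[str | None, int | None]:
            if label is None or "$" not in label:
                return label, None
            base, _, tag = label.rpartition("$")
            try:
                return (base or None), int(tag)
            except ValueError:
                return label, None

        def convert(dnode) -> Node:
            raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
            base, tag = strip_tag(raw)
            support = None
            name = base
            if dnode.child_nodes() and base is not None:
                try:
                    support = float(base)
                    name = None
                except ValueError:
                    pass
            node = Node(name=name, length=dnode.edge.length, support=support)
            node.partition = tag if tag is not None else -1  # -1: inherit
            for dch in dnode.child_nodes():
                node.add(convert(dch))
            return node

        root = convert(dt.seed_node)
        tree = cls(root)
        # propagate subtree tag semantics; untagged root branches are 0
        for node in tree.preorder():
            if node.partition == -1:
                node.partition = node.parent.partition if node.parent else 0
        root.length = None
        root.partition = 0
        return tree

    def to_newick(self, include_support: bool = True) -> str:
        def fmt_len(x) -> str:
            return "" if x is None else f":{x:.10g}"

        def tag(n: Node) -> str:
            parent_part = n.parent.partition if n.parent else 0
            return f"${n.partition}" if n.partition != parent_part else ""

        def rec(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}{tag(n)}{fmt_len(n.length)}"
            inner = ",".join(rec(c) for c in n.children)
            label = ""
            if include_support and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}{tag(n)}{fmt_len(n.length)}"

        return rec(self.root) + ";"

    # -- structure ---------------------------------------------------------

    def bipartitions(self, min_length: float | None = None) -> set[frozenset]:
        """Canonical internal-edge splits: for each internal edge, the leaf
        set on the side *not* containing the alphabetically first taxon.

        With ``min_length``, edges no longer than that are treated as
        unresolved and skipped (a zero-length internal branch carries no
        grouping signal).
        """
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)
        below: dict[int, set] = {}
        splits = set()
        for n in self.postorder():
            s = {n.name} if n.is_leaf else set().union(
                *(below[id(c)] for c in n.children)
            )
            below[id(n)] = s
            if n.parent is not None and not n.is_leaf and 2 <= len(s) <= len(all_leaves) - 2:
                if min_length is not None and (n.length or 0.0) <= min_length:
                    continue
                side = all_leaves - s if ref in s else s
                splits.add(frozenset(side))
        return splits

    def clade_leafsets(self) -> dict[int, frozenset]:
        """id(node) -> leaf-name set below that node."""
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            below[id(n)] = (
                frozenset([n.name])
                if n.is_leaf
                else frozenset().union(*(below[id(c)] for c in n.children))
            )
        return below

    def ladderized_leaf_order(self, ascending: bool = True) -> list[str]:
        def size(n: Node) -> int:
            return 1 if n.is_leaf else sum(size(c) for c in n.children)

        def rec(n: Node) -> list[str]:
            if n.is_leaf:
                return [n.name]
            kids = sorted(
                n.children, key=lambda c: (size(c), min(self._leafset(c))),
                reverse=not ascending,
            )
            out = []
            for c in kids:
                out.extend(rec(c))
            return out

        return rec(self.root)

    def _leafset(self, n: Node) -> set:
        out, stack = set(), [n]
        while stack:
            m = stack.pop()
            if m.is_leaf:
                out.add(m.name)
            else:
                stack.extend(m.children)
        return out

    def rerooted_at_leaf(self, name: str) -> "LabeledTree":
        """Copy of the tree re-hung so the named leaf's parent is the root.

        Branch attributes stay attached to the same physical edge; nodes left
        with a single child by the re-hang are spliced out (lengths summed).
        """
        tree = self.copy()
        target = tree.find_leaf(name).parent
        path = []
        n = target
        while n is not None:
            path.append(n)
            n = n.parent
        attrs = [(m.length, m.partition, m.support) for m in path]
        for i in range(len(path) - 1, 0, -1):
            parent, child = path[i], path[i - 1]
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
            parent.length, parent.partition, parent.support = attrs[i - 1]
        target.parent = None
        target.length, target.support = None, None
        target.partition = 0
        out = LabeledTree(target)
        out._suppress_unifurcations()
        return out

    def _suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for n in self.preorder():
                if n.parent is not None and len(n.children) == 1:
                    (ch,) = n.children
                    ch.length = (ch.length or 0) + (n.length or 0)
                    ch.partition = n.partition
                    p = n.parent
                    p.children[p.children.index(n)] = ch
                    ch.parent = p
                    changed = True
                    break
        if len(self.root.children) == 1 and not self.root.is_leaf:
            (ch,) = self.root.children
            if not ch.is_leaf:
                ch.parent = None
                ch.length = None
                ch.partition = 0
                self.root = ch


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) over ordered taxa."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal in distance matrix")
        if np.any(self.d[np.isfinite(self.d)] < 0):
            raise ValueError("negative distances")
        if not np.array_equal(
            np.nan_to_num(self.d, posinf=1e12),
            np.nan_to_num(self.d.T, posinf=1e12),
        ):
            raise ValueError("distance matrix is not symmetric")


_MISSING = {
    "protein": frozenset("-X*"),
    "nucleotide": frozenset("-NRYSWKMBDHV"),
}


def _pdist_from_matrix(mat: np.ndarray, alphabet: str) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of gap/ambiguous columns."""
    miss = _MISSING[alphabet]
    ok = ~np.isin(mat, list(miss))
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between rows {i} and {j}"
                )
            p = float((mat[i][both] != mat[j][both]).sum()) / m
            d[i, j] = d[j, i] = p
    return d


def p_distance(alignment, model: str | None = None) -> DistanceMatrix:
    """Pairwise distance matrix under ``p``, ``poisson`` (protein) or ``jc``
    (nucleotide) corrections; default is the uncorrected p-distance.

    Columns gapped or ambiguous in either member of a pair are excluded from
    that pair's comparison. Distances beyond a correction's domain saturate
    to infinity with a warning.
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    is_protein = isinstance(alignment, ProteinAlignment)
    mat = alignment.to_matrix()
    d = _pdist_from_matrix(mat, "protein" if is_protein else "nucleotide")
    d = _apply_correction(d, model, is_protein)
    return DistanceMatrix(list(alignment.taxa), d)


def _apply_correction(d: np.ndarray, model: str | None, is_protein: bool) -> np.ndarray:
    model = model or "p"
    valid = {"p", "poisson"} if is_protein else {"p", "jc"}
    if model not in valid:
        raise ValueError(f"model {model!r} not valid for this alignment type")
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "poisson":
            d = -np.log(1.0 - d)
        elif model == "jc":
            arg = 1.0 - 4.0 * d / 3.0
            d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.inf)
    d = np.where(np.isnan(d), np.inf, d)
    np.fill_diagonal(d, 0.0)
    if np.isinf(d).any():
        warnings.warn("saturated distances set to infinity", RuntimeWarning)
    return d


def neighbor_joining(dm: DistanceMatrix) -> LabeledTree:
    """Saitou–Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the lowest (i, j)
    index pair in the input taxon order (new internal nodes append after).
    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling branch, preserving the pair's path length. Returns
    an unrooted tree (trifurcating root).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    d = dm.d.copy()
    nodes = [Node(name=t) for t in dm.taxa]
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = q[a, b]
                if best is None or key < best[0] - 1e-12:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        u = Node()
        u.add(nodes[i]).length = li
        u.add(nodes[j]).length = lj
        nodes.append(u)
        knew = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[knew, c] = d[c, knew] = 0.5 * (d[i, c] + d[j, c] - dij)
        active = [c for c in active if c not in (i, j)] + [knew]

    i, j, k = active
    root = Node()
    la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, la), (j, lb), (k, lc)):
        root.add(nodes[idx]).length = max(ln, 0.0)
        nodes[idx].length = max(ln, 0.0)
    return LabeledTree(root)


def bootstrap_support(
    alignment,
    n_reps: int = 500,
    seed: int = 0,
    model: str | None = None,
    collapse: float | None = 70.0,
) -> LabeledTree:
    """NJ tree with nonparametric bootstrap supports on internal branches.

    Columns are resampled with replacement ``n_reps`` times; support is the
    percentage of replicates containing each original internal bipartition.
    Branches with support below ``collapse`` (percent) are collapsed into
    multifurcations; pass ``collapse=None`` to keep the binary tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = list(alignment.taxa)
    mat = alignment.to_matrix()
    alphabet = "protein" if isinstance(alignment, ProteinAlignment) else "nucleotide"
    # canonical taxon order (sorted by name) makes the base tree, the
    # resampling stream and the NJ tie-breaking input-order independent
    order = np.argsort(np.array(taxa))
    mat_sorted = mat[order]
    taxa_sorted = [taxa[i] for i in order]
    is_protein = isinstance(alignment, ProteinAlignment)
    tree = neighbor_joining(
        DistanceMatrix(
            taxa_sorted,
            _apply_correction(_pdist_from_matrix(mat_sorted, alphabet), model, is_protein),
        )
    )
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ncol = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        try:
            drep = _apply_correction(
                _pdist_from_matrix(mat_sorted[:, cols], alphabet), model, is_protein
            )
            rep_tree = neighbor_joining(DistanceMatrix(taxa_sorted, drep))
        except ValueError:  # incomparable pair or saturation in this draw
            continue
        # zero-length replicate branches are unresolved, not evidence
        for split in rep_tree.bipartitions(min_length=1e-12):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = set(taxa)
    ref = min(all_leaves)
    below = tree.clade_leafsets()
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        s = below[id(node)]
        if not (2 <= len(s) <= len(all_leaves) - 2):
            continue
        side = frozenset(all_leaves - s) if ref in s else s
        node.support = 100.0 * counts.get(side, 0) / n_reps
    if collapse is not None:
        _collapse_low_support(tree, collapse)
    return tree


def _collapse_low_support(tree: LabeledTree, threshold: float) -> None:
    changed = True
    while changed:
        changed = False
        for node in tree.preorder():
            if (
                node.parent is not None
                and not node.is_leaf
                and node.support is not None
                and node.support < threshold
            ):
                p = node.parent
                idx = p.children.index(node)
                p.children[idx : idx + 1] = node.children
                for ch in node.children:
                    ch.parent = p
                changed = True
                break


def read_partition_map(path) -> dict[str, int]:
    """Read a TSV of ``taxon<TAB>partition`` rows."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, part = line.split("\t")[:2]
            out[taxon] = int(part)
    return out


def label_clades(tree: LabeledTree, mapping: dict[str, int]) -> LabeledTree:
    """Label every branch of the tree with its clade partition.

    ``mapping`` assigns each leaf an integer partition (0 = background).
    Each non-background partition's leaf set must be monophyletic in the
    unrooted tree; its stem branch and all branches within its subtree get
    the partition label, all other branches label 0. Raises ``ValueError``
    listing the offending leaves for a non-monophyletic partition.
    """
    names = set(tree.leaf_names())
    missing = names - set(mapping)
    if missing:
        raise ValueError(f"partition map is missing leaves: {sorted(missing)}")
    vals = set(mapping.values())
    if vals != set(range(max(vals) + 1)):
        raise ValueError(
            f"partition labels must be contiguous from 0, got {sorted(vals)}"
        )
    nonzero = [k for k in sorted(vals) if k != 0]
    background = [t for t in names if mapping[t] == 0]
    if nonzero and not background:
        raise ValueError("need at least one background (partition 0) leaf")
    out = tree.copy()
    if nonzero:
        out = out.rerooted_at_leaf(background[0])
    for node in out.preorder():
        node.partition = 0
    below = out.clade_leafsets()
    for k in nonzero:
        want = frozenset(t for t, v in mapping.items() if v == k)
        anchor = None
        for node in out.preorder():
            if below[id(node)] == want:
                anchor = node
                break
        if anchor is None:
            raise ValueError(
                f"partition {k} is not monophyletic; leaves: {sorted(want)}"
            )
        stack = [anchor]
        while stack:
            n = stack.pop()
            n.partition = k
            stack.extend(n.children)
    return out


def merge_partitions(tree: LabeledTree, mapping: dict[int, int]) -> LabeledTree:
    """Relabel branch partitions by merging (e.g. ``{0: 0, 1: 1, 2: 1}``).

    Operating on branch labels (not leaf sets) keeps the merged configuration
    nested inside the original: every branch keeps its membership, only the
    label identities coarsen. Deriving a merged labeling from leaf monophyly
    instead would absorb the merged clade's stem branch and break nesting.
    """
    out = tree.copy()
    for node in out.preorder():
        node.partition = mapping.get(node.partition, node.partition)
    labels = {n.partition for n in out.preorder()}
    if labels != set(range(max(labels) + 1)):
        raise ValueError(f"merged labels not contiguous from 0: {sorted(labels)}")
    return out


def path_length_matrix(tree: LabeledTree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    leaves = tree.leaves()
    names = [n.name for n in leaves]

    def ancestors(n: Node) -> dict[int, float]:
        out, dist = {}, 0.0
        while n is not None:
            out[id(n)] = dist
            dist += n.length or 0.0
            n = n.parent
        return out

    anc = [ancestors(n) for n in leaves]
    m = len(leaves)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            shared = [k for k in anc[i] if k in anc[j]]
            dij = min(anc[i][k] + anc[j][k] for k in shared)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(names, d)
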