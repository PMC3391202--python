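"""Rooted time trees: Newick/NEXUS I/O, grafting, fossil calibration and pruning.

Ages are stored in Ma before present (larger = older).  Branch durations are
always *derived* as ``age(parent) - age(child)`` once a tree has been
time-scaled; before scaling, the branch lengths read from the input file are
the only length information.  This prevents ages and durations from drifting
out of sync.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "TreeNode",
    "CalibrationTable",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "read_nexus_trees",
    "graft_subtree",
    "time_scale",
    "resolve_zero_branches",
    "prune",
]


class TreeError(ValueError):
    """Structural or calibration error on a tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick/NEXUS input; the message names the offending token."""


class TreeNode:
    """A node in a rooted tree. ``length`` is the input branch length (may be
    None); ``age`` is in Ma before present (None until the tree is dated)."""

    __slots__ = ("label", "parent", "children", "length", "age")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.length = length
        self.age: Optional[float] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def duration(self) -> Optional[float]:
        """Branch duration above this node (Myr), derived from ages when dated."""
        if self.parent is None:
            return None
        if self.age is not None and self.parent.age is not None:
            return self.parent.age - self.age
        return self.length

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r}, age={self.age})"


class TimeTree:
    """A rooted tree whose nodes may carry ages (Ma before present)."""

    def __init__(self, root: TreeNode):
        self.root = root

    # ---------------------------------------------------------------- traversal
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    def find_tip(self, label: str) -> TreeNode:
        for n in self.tips():
            if n.label == label:
                return n
        raise TreeError(f"tip label not found: {label!r}")

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        seen: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                seen[node] = {node.label} & want
            else:
                seen[node] = set().union(*(seen[c] for c in node.children))
            if seen[node] == want:
                return node
        raise TreeError(f"tips not all present: {sorted(want)}")

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    @property
    def has_ages(self) -> bool:
        return all(n.age is not None for n in self.preorder())

    # ------------------------------------------------------------------- copy
    def copy(self) -> "TimeTree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            new.age = node.age
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return TimeTree(_clone(self.root))

    # ----------------------------------------------------------------- dating
    def assign_ages_from_lengths(self) -> "TimeTree":
        """Date nodes from branch lengths: the root sits at the depth of the
        deepest tip and every node at root_age minus its root-to-node path."""
        depth: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                if node.length is None:
                    raise TreeError("cannot assign ages: branch length missing")
                depth[node] = depth[node.parent] + node.length
        height = max(depth[t] for t in self.tips())
        for node in self.preorder():
            node.age = height - depth[node]
        return self

    def check_ages(self, strict: bool = True) -> None:
        """Assert parent age >= child age on every edge."""
        for node in self.preorder():
            if node.parent is None:
                continue
            d = node.duration
            if d is None:
                raise TreeError(f"undated edge above {node.label!r}")
            if d < 0:
                raise TreeError(
                    f"negative branch duration ({d:.6g} Myr) above {node.label!r}"
                )
            if strict and d == 0:
                raise TreeError(f"zero-length branch above {node.label!r}")

    # ------------------------------------------------------------- distances
    def patristic_distances(self, labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Pairwise path-length (patristic) distances among tips.

        Uses ages when the tree is dated, branch lengths otherwise.
        """
        tips = self.tips()
        if labels is not None:
            by_label = {t.label: t for t in tips}
            tips = [by_label[l] for l in labels]
        depth: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                d = node.duration
                if d is None:
                    raise TreeError("tree has neither ages nor branch lengths")
                depth[node] = depth[node.parent] + d

        # map each tip to its ancestor path for LCA depth lookup
        anc: dict[TreeNode, list[TreeNode]] = {}
        for t in tips:
            path = []
            n: Optional[TreeNode] = t
            while n is not None:
                path.append(n)
                n = n.parent
            anc[t] = path
        index = {id(n): i for t in tips for i, n in enumerate(anc[t])}

        n = len(tips)
        out = np.zeros((n, n))
        for i in range(n):
            anc_i = {id(a): depth[a] for a in anc[tips[i]]}
            for j in range(i + 1, n):
                lca_depth = next(
                    anc_i[id(a)] for a in anc[tips[j]] if id(a) in anc_i
                )
                out[i, j] = out[j, i] = depth[tips[i]] + depth[tips[j]] - 2 * lca_depth
        labs = [t.label for t in tips]
        return pd.DataFrame(out, index=labs, columns=labs)

    def shared_path_matrix(self, labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Brownian-motion tip covariance structure: V[i,j] = shared root-to-LCA
        path length, V[i,i] = root-to-tip path length."""
        tips = self.tips()
        if labels is not None:
            by_label = {t.label: t for t in tips}
            tips = [by_label[l] for l in labels]
        depth: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[node] = depth[node.parent] + node.duration
        anc: dict[TreeNode, dict[int, float]] = {}
        paths: dict[TreeNode, list[TreeNode]] = {}
        for t in tips:
            path = []
            n: Optional[TreeNode] = t
            while n is not None:
                path.append(n)
                n = n.parent
            paths[t] = path
            anc[t] = {id(a): depth[a] for a in path}
        n = len(tips)
        out = np.zeros((n, n))
        for i in range(n):
            out[i, i] = depth[tips[i]]
            for j in range(i + 1, n):
                lca_depth = next(
                    anc[tips[i]][id(a)] for a in paths[tips[j]] if id(a) in anc[tips[i]]
                )
                out[i, j] = out[j, i] = lca_depth
        labs = [t.label for t in tips]
        return pd.DataFrame(out, index=labs, columns=labs)

    # -------------------------------------------------------------------- I/O
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        def _convert(dnode) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(label, dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(_convert(child))
            return node

        root = _convert(dtree.seed_node)
        root.length = None
        tree = cls(root)
        seen: set[str] = set()
        for tip in tree.tips():
            if tip.label is None:
                raise NewickParseError("unlabeled tip in input tree")
            if tip.label in seen:
                raise NewickParseError(f"duplicate tip label: {tip.label!r}")
            seen.add(tip.label)
        return tree

    def to_newick(self, precision: int = 10, include_lengths: bool = True) -> str:
        def _fmt(node: TreeNode) -> str:
            if node.is_tip:
                s = _escape(node.label)
            else:
                s = "(" + ",".join(_fmt(c) for c in node.children) + ")"
                if node.label:
                    s += _escape(node.label)
            if include_lengths and node.parent is not None:
                d = node.duration
                if d is not None:
                    s += f":{d:.{precision}g}"
            return s

        return _fmt(self.root) + ";"

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree with {len(self.tips())} tips>"


def _escape(label: Optional[str]) -> str:
    if label is None:
        return ""
    if any(c in label for c in "(),:;[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(text: str) -> TimeTree:
    """Parse a rooted Newick string into a :class:`TimeTree`.

    Branch lengths and internal labels are preserved; ages remain unset until
    :func:`time_scale` or :meth:`TimeTree.assign_ages_from_lengths` runs.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return TimeTree.from_dendropy(dtree)


def read_nexus_trees(text: str) -> list[TimeTree]:
    """Read every tree in a NEXUS ``trees`` block."""
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed NEXUS trees block: {exc}") from exc
    return [TimeTree.from_dendropy(t) for t in trees]


# ---------------------------------------------------------------------------
# calibration table
# ---------------------------------------------------------------------------

@dataclass
class CalibrationRow:
    taxon: str
    fo_ma: float
    lo_ma: float
    mrca_of: Optional[str] = None      # "tipA|tipB" naming an internal node
    node_date_ma: Optional[float] = None

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.fo_ma + self.lo_ma)

    @property
    def is_extant(self) -> bool:
        return self.lo_ma == 0.0


@dataclass
class CalibrationTable:
    """First/last occurrence ages per taxon plus optional molecular node dates.

    Molecular dates attach to internal nodes through ``mrca_of``, a pair of tip
    labels separated by ``|``; the date is applied to their most recent common
    ancestor.
    """

    rows: dict[str, CalibrationRow] = field(default_factory=dict)
    node_dates: list[CalibrationRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for row in list(self.rows.values()) + self.node_dates:
            if not (np.isfinite(row.fo_ma) and np.isfinite(row.lo_ma)):
                raise TreeError(f"non-finite age for {row.taxon!r}")
            if row.fo_ma < row.lo_ma or row.lo_ma < 0:
                raise TreeError(
                    f"calibration for {row.taxon!r} violates "
                    f"first >= last >= 0: ({row.fo_ma}, {row.lo_ma})"
                )

    def __getitem__(self, taxon: str) -> CalibrationRow:
        try:
            return self.rows[taxon]
        except KeyError:
            raise TreeError(f"missing calibration row for taxon {taxon!r}") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.rows

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationTable":
        rows: dict[str, CalibrationRow] = {}
        node_dates: list[CalibrationRow] = []
        for _, r in df.iterrows():
            mrca = r.get("mrca_of")
            if isinstance(mrca, float) and np.isnan(mrca):
                mrca = None
            nd = r.get("node_date_ma")
            if nd is not None and (isinstance(nd, float) and np.isnan(nd)):
                nd = None
            row = CalibrationRow(
                taxon=str(r["taxon"]),
                fo_ma=float(r["fo_ma"]),
                lo_ma=float(r["lo_ma"]),
                mrca_of=mrca,
                node_date_ma=None if nd is None else float(nd),
            )
            if row.mrca_of:
                node_dates.append(row)
            else:
                rows[row.taxon] = row
        return cls(rows=rows, node_dates=node_dates)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CalibrationTable":
        return cls.from_frame(pd.read_csv(path_or_buf))

    def to_frame(self) -> pd.DataFrame:
        recs = [
            dict(taxon=r.taxon, fo_ma=r.fo_ma, lo_ma=r.lo_ma,
                 mrca_of=r.mrca_of, node_date_ma=r.node_date_ma)
            for r in list(self.rows.values()) + self.node_dates
        ]
        return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------

def graft_subtree(host: TimeTree, otu_label: str, donor: TimeTree) -> TimeTree:
    """Replace a terminal OTU of ``host`` by the whole ``donor`` tree.

    This is how a supraspecific placeholder tip (e.g. a subfamily coded as one
    OTU in a cladistic matrix) is expanded into a resolved species-level tree
    to build a composite phylogeny.  The donor root inherits the branch that
    led to the replaced tip.  Node ages are cleared: a composite tree must be
    re-dated by :func:`time_scale`.
    """
    result = host.copy()
    target = None
    for node in result.preorder():
        if node.label == otu_label:
            if not node.is_tip:
                raise TreeError(f"{otu_label!r} is an internal node, not a tip")
            target = node
            break
    if target is None:
        raise TreeError(f"tip label not found: {otu_label!r}")

    clone = donor.copy()
    new = clone.root
    new.length = target.length
    parent = target.parent
    if parent is None:
        result = TimeTree(new)
    else:
        parent.children[parent.children.index(target)] = new
        new.parent = parent

    host_labels = set(host.tip_labels()) - {otu_label}
    overlap = host_labels & set(donor.tip_labels())
    if overlap:
        raise TreeError(f"duplicate tip labels after graft: {sorted(overlap)}")
    for node in result.preorder():
        node.age = None
    return result


# ---------------------------------------------------------------------------
# time scaling
# ---------------------------------------------------------------------------

def time_scale(
    tree: TimeTree,
    cal: CalibrationTable,
    mode: str = "main",
    extend_extant: bool = True,
    zero_policy: str = "share",
    epsilon: float = 0.1,
) -> TimeTree:
    """Date a tree from fossil occurrences and optional molecular node dates.

    Three calibration modes are supported; in each, internal nodes are then set
    to ``max(molecular date, oldest descendant constraint)`` by a post-order
    pass, which guarantees parent age >= child age everywhere:

    ``main``
        Fossil tips sit at the midpoint of their stratigraphic range; extant
        tips constrain their parents by first occurrence and are extended to
        the present (age 0) when ``extend_extant`` (else dated at first
        occurrence).
    ``range``
        Nodes are constrained by first occurrences and every terminal branch
        extends to its last occurrence (0 for extant taxa).
    ``midpoint``
        Every taxon is dated at the midpoint of its range, with the present
        taken as the upper margin for extant taxa.

    Zero-duration branches produced by shared constraint ages are removed by
    :func:`resolve_zero_branches` with the given policy.
    """
    if mode not in ("main", "range", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    result = tree.copy()
    tips = result.tips()
    # constraint age dates parents; final age positions the tip itself
    constraint: dict[int, float] = {}
    final: dict[int, float] = {}
    for tip in tips:
        row = cal[tip.label]
        if mode == "main":
            if row.is_extant:
                constraint[id(tip)] = row.fo_ma
                final[id(tip)] = 0.0 if extend_extant else row.fo_ma
            else:
                constraint[id(tip)] = final[id(tip)] = row.midpoint
        elif mode == "range":
            constraint[id(tip)] = row.fo_ma
            final[id(tip)] = row.lo_ma
        else:  # midpoint
            constraint[id(tip)] = final[id(tip)] = row.midpoint

    mol_dates: dict[int, float] = {}
    for row in cal.node_dates:
        if row.node_date_ma is None:
            continue
        pair = [s.strip() for s in row.mrca_of.split("|")]
        if len(pair) != 2:
            raise TreeError(f"mrca_of must name two tips: {row.mrca_of!r}")
        present = [p for p in pair if p in set(result.tip_labels())]
        if len(present) < 2:
            continue  # calibration refers to pruned taxa
        node = result.mrca(pair)
        mol_dates[id(node)] = max(mol_dates.get(id(node), 0.0), row.node_date_ma)

    pushed: list[str] = []
    for node in result.postorder():
        if node.is_tip:
            node.age = constraint[id(node)]
            continue
        oldest_child = max(c.age for c in node.children)
        mol = mol_dates.get(id(node))
        if mol is not None and mol < oldest_child:
            pushed.append(node.label or "<unnamed>")
        node.age = oldest_child if mol is None else max(mol, oldest_child)
    if pushed:
        warnings.warn(
            "molecular date younger than fossil constraint at node(s) "
            f"{pushed}; fossil date used", stacklevel=2,
        )
    for tip in tips:
        tip.age = final[id(tip)]
    result.check_ages(strict=False)
    result = resolve_zero_branches(result, policy=zero_policy, epsilon=epsilon)
    result.check_ages(strict=True)
    return result


def resolve_zero_branches(
    tree: TimeTree, policy: str = "share", epsilon: float = 0.1
) -> TimeTree:
    """Remove zero-duration branches from a dated tree.

    ``share`` redistributes the duration of the nearest positive ancestral
    branch equally along the zero-length chain below it, keeping the ages of
    the chain's bottom node (and hence all root-to-tip ages of unaffected
    tips) unchanged.  ``epsilon`` instead pushes each zero-duration child
    ``epsilon`` Myr younger than its parent.
    """
    if policy not in ("share", "epsilon"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "epsilon" and not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    result = tree.copy()
    if not result.has_ages:
        raise TreeError("resolve_zero_branches requires a dated tree")

    if policy == "epsilon":
        for node in result.preorder():
            if node.parent is not None and node.duration <= 0:
                node.age = node.parent.age - epsilon
        result.check_ages(strict=True)
        return result

    changed = True
    while changed:
        changed = False
        # deepest-first so a full zero chain is collected from its bottom
        for node in result.postorder():
            if node.parent is None or node.duration > 0:
                continue
            # climb the zero chain to the nearest positive ancestral branch
            chain = [node]
            top = node.parent
            while top.parent is not None and top.duration == 0:
                chain.append(top)
                top = top.parent
            if top.parent is None:
                raise TreeError(
                    "zero-length chain reaches the root; no positive "
                    "ancestral branch to share from"
                )
            d = top.duration
            share = d / (len(chain) + 1)
            # walk down from top, spacing nodes evenly; bottom age unchanged
            age = top.parent.age
            for nd in [top] + list(reversed(chain[1:])):
                age -= share
                nd.age = age
            changed = True
            break
    result.check_ages(strict=True)
    return result


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Restrict a tree to a subset of tips.

    Unary internal nodes created by tip removal are collapsed (branch
    durations summed); node ages, and hence patristic distances among kept
    tips, are preserved exactly.
    """
    keep = set(keep)
    have = set(tree.tip_labels())
    unknown = keep - have
    if unknown:
        raise TreeError(f"unknown tip label(s): {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("must keep at least two tips")

    result = tree.copy()
    # drop unwanted tips, then childless internals, bottom-up
    retained: dict[TreeNode, bool] = {}
    for node in result.postorder():
        if node.is_tip:
            retained[node] = node.label in keep
        else:
            node.children = [c for c in node.children if retained[c]]
            retained[node] = bool(node.children)
    # collapse unary internal nodes
    def _collapse(node: TreeNode) -> TreeNode:
        while len(node.children) == 1:
            child = node.children[0]
            if node.age is None and node.length is not None and child.length is not None:
                child.length = node.length + child.length
            child.parent = node.parent
            node = child
        node.children = [_collapse(c) for c in node.children]
        for c in node.children:
            c.parent = node
        return node

    new_root = _collapse(result.root)
    new_root.parent = None
    new_root.length = None
    return TimeTree(new_root)
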