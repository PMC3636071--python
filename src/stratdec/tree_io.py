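"""Dated ultrametric trees, posterior samples, and epoch-aware branch slicing.

Trees are rooted, strictly binary, and ultrametric with branch lengths in
millions of years; node ages are measured in Ma before present (tips at 0).
dendropy handles newick/NEXUS parsing and serialization; this module keeps a
lightweight age-indexed structure on top of it because everything downstream
(likelihoods, simulation, jittering) works directly with node ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np
from scipy import stats

from .geography import ConfigError, EpochModel

__all__ = [
    "TreeError",
    "Node",
    "DatedTree",
    "TreeSample",
    "CalibrationPrior",
    "read_trees",
    "prune_taxa",
    "clade_age_summary",
    "hpd_interval",
    "slice_branch",
    "lognormal_calibration",
]

#: Relative ultrametricity tolerance (fraction of root age); consensus trees
#: typically carry rounding noise at the 1e-8 level.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Malformed or unsupported tree input."""


class Node:
    """Tree node with an age in Ma; binary internal nodes, tips at age 0."""

    __slots__ = ("label", "age", "children", "parent")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.label = label
        self.age = age
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def branch_duration(self) -> float:
        """Duration in Myr of the branch subtending this node."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age


class DatedTree:
    """A rooted binary ultrametric tree with node ages in Ma."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "DatedTree":
        seed = tree.seed_node
        for nd in tree.preorder_node_iter():
            n_ch = len(nd.child_nodes())
            if nd is not seed and n_ch not in (0, 2):
                raise TreeError(
                    f"tree is not strictly binary (node with {n_ch} children)"
                )
        if len(seed.child_nodes()) != 2:
            raise TreeError("root must be binary (is the tree rooted?)")
        # depth = distance from root; age = height - depth
        depth: dict[dendropy.Node, float] = {seed: 0.0}
        height = 0.0
        for nd in tree.preorder_node_iter():
            if nd is seed:
                continue
            el = nd.edge.length
            if el is None:
                raise TreeError("tree has a branch without a length")
            if el <= 0:
                raise TreeError(f"non-positive branch length {el}")
            depth[nd] = depth[nd.parent_node] + el
            if not nd.child_nodes():
                height = max(height, depth[nd])
        tol = ULTRAMETRIC_RTOL * height
        for nd in tree.leaf_node_iter():
            if abs(depth[nd] - height) > tol:
                name = nd.taxon.label if nd.taxon else "?"
                raise TreeError(
                    f"tree is not ultrametric: tip {name!r} at depth "
                    f"{depth[nd]:.6g} vs root height {height:.6g}"
                )

        def convert(dnd: dendropy.Node) -> Node:
            if dnd.child_nodes():
                node = Node(label=None, age=height - depth[dnd])
                for ch in dnd.child_nodes():
                    node.add_child(convert(ch))
            else:
                label = dnd.taxon.label if dnd.taxon else dnd.label
                if label is None:
                    raise TreeError("unlabeled tip")
                node = Node(label=str(label), age=0.0)
            return node

        return cls(convert(seed))

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def _validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if len(labels) < 2:
            raise TreeError("tree needs at least two tips")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        for nd in self.preorder():
            if not nd.is_tip and len(nd.children) != 2:
                raise TreeError("internal nodes must be binary")
            if nd.parent is not None and nd.parent.age <= nd.age - 1e-12:
                raise TreeError(
                    f"node age {nd.age} not younger than parent {nd.parent.age}"
                )

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        yield from reversed(out)

    def tips(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [nd for nd in self.postorder() if not nd.is_tip]

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tips())

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def root_age(self) -> float:
        return self.root.age

    # -- clades -------------------------------------------------------------

    def clade_map(self) -> dict[frozenset[str], Node]:
        """Map from tip-label set to the MRCA node, for every node."""
        below: dict[Node, frozenset[str]] = {}
        out: dict[frozenset[str], Node] = {}
        for nd in self.postorder():
            if nd.is_tip:
                below[nd] = frozenset([nd.label])
            else:
                below[nd] = frozenset().union(*(below[c] for c in nd.children))
            out[below[nd]] = nd
        return out

    def find_clade(self, clade: frozenset[str]) -> Node | None:
        """The node whose descendant tip set equals ``clade``, if any."""
        return self.clade_map().get(frozenset(clade))

    # -- serialization ------------------------------------------------------

    def copy(self) -> "DatedTree":
        def dup(nd: Node) -> Node:
            new = Node(nd.label, nd.age)
            for c in nd.children:
                new.add_child(dup(c))
            return new

        return DatedTree(dup(self.root))

    def to_newick(self, precision: int = 10) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_tip:
                core = nd.label
            else:
                core = "(" + ",".join(fmt(c) for c in nd.children) + ")"
            if nd.parent is None:
                return core
            return f"{core}:{nd.branch_duration:.{precision}f}"

        return fmt(self.root) + ";"


@dataclass
class TreeSample:
    """A (posterior) sample of dated trees over one shared tip set."""

    trees: list[DatedTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        labels = self.trees[0].tip_labels
        for i, t in enumerate(self.trees[1:], start=1):
            if t.tip_labels != labels:
                raise TreeError(
                    f"tree {i} has a different tip set from tree 0"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[DatedTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> DatedTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> frozenset[str]:
        return self.trees[0].tip_labels


def read_trees(path: str | Path, schema: str | None = None) -> TreeSample:
    """Read one or more dated trees from a newick or NEXUS file."""
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".trees", ".t"} else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    if not tl:
        raise TreeError(f"no trees found in {path}")
    return TreeSample([DatedTree.from_dendropy(t) for t in tl])


def write_trees(sample: TreeSample | DatedTree, path: str | Path) -> Path:
    path = Path(path)
    trees = sample.trees if isinstance(sample, TreeSample) else [sample]
    text = "\n".join(t.to_newick() for t in trees) + "\n"
    if path.suffix.lower() in {".nex", ".nexus", ".trees"}:
        tl = dendropy.TreeList.get(data=text, schema="newick")
        tl.write(path=str(path), schema="nexus")
    else:
        path.write_text(text)
    return path


def prune_taxa(tree: DatedTree, drop: Iterable[str]) -> DatedTree:
    """Remove the given tips, suppressing degree-2 nodes; ages are untouched.

    Branch durations across a suppressed node sum, so pairwise divergence
    ages among surviving tips are preserved exactly.
    """
    drop = set(drop)
    present = tree.tip_labels
    unknown = drop - present
    if unknown:
        raise TreeError(f"cannot drop unknown tips: {sorted(unknown)}")
    if len(present - drop) < 2:
        raise TreeError("pruning would leave fewer than two tips")
    if not drop:
        return tree.copy()

    def build(nd: Node) -> Node | None:
        if nd.is_tip:
            if nd.label in drop:
                return None
            return Node(nd.label, nd.age)
        kept = [c for c in (build(ch) for ch in nd.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]  # suppress degree-2 node; child keeps its own age
        new = Node(None, nd.age)
        for c in kept:
            new.add_child(c)
        return new

    root = build(tree.root)
    assert root is not None
    return DatedTree(root)


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the empirical sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass(frozen=True)
class CladeAgeSummary:
    median: float
    hpd_low: float
    hpd_high: float
    clade_frequency: float


def clade_age_summary(
    sample: TreeSample, clade: Iterable[str], mass: float = 0.95
) -> CladeAgeSummary:
    """Median age and shortest 95% interval of a clade across a tree sample.

    Only trees actually containing the clade contribute ages; the fraction of
    trees containing it is reported alongside as the clade frequency.
    """
    key = frozenset(clade)
    ages = []
    for t in sample:
        nd = t.find_clade(key)
        if nd is not None:
            ages.append(nd.age)
    if not ages:
        raise TreeError("clade not present in any tree of the sample")
    lo, hi = hpd_interval(ages, mass)
    return CladeAgeSummary(
        median=float(np.median(ages)),
        hpd_low=lo,
        hpd_high=hi,
        clade_frequency=len(ages) / len(sample),
    )


def slice_branch(
    parent_age: float, child_age: float, epochs: EpochModel
) -> list[tuple[float, int]]:
    """Cut a branch into per-epoch segments, ordered old -> young.

    Returns ``[(duration_Myr, slice_index), ...]``; durations sum exactly to
    the branch length.
    """
    if parent_age <= child_age:
        raise TreeError(
            f"parent age {parent_age} must exceed child age {child_age}"
        )
    if child_age < 0:
        raise TreeError("child age below 0 Ma")
    if parent_age > epochs.oldest_bound + 1e-9:
        raise ConfigError(
            f"branch starts at {parent_age} Ma, beyond the epoch span "
            f"({epochs.oldest_bound} Ma); validate_epochs first"
        )
    segments: list[tuple[float, int]] = []
    t = parent_age
    for i, s in enumerate(epochs.slices):
        if t <= s.younger_bound:
            continue
        lo = max(child_age, s.younger_bound)
        if t > lo:
            segments.append((t - lo, i))
            t = lo
        if t <= child_age:
            break
    # make durations sum exactly to the branch length
    total = sum(d for d, _ in segments)
    err = (parent_age - child_age) - total
    if segments and abs(err) > 0:
        d, i = segments[-1]
        segments[-1] = (d + err, i)
    return segments


@dataclass(frozen=True)
class CalibrationPrior:
    """Offset lognormal prior for a fossil minimum-age calibration.

    The density lives on ages older than ``offset`` (the fossil's minimum
    age); ``mu``/``sigma`` are the log-scale parameters of the excess age, and
    ``tail_span`` is the distance in Myr from the offset to the 95% quantile.
    """

    offset: float
    mu: float
    sigma: float
    tail_span: float

    def quantile(self, q: float) -> float:
        return self.offset + float(
            stats.lognorm.ppf(q, s=self.sigma, scale=math.exp(self.mu))
        )

    def pdf(self, age: float | np.ndarray) -> np.ndarray:
        return stats.lognorm.pdf(
            np.asarray(age) - self.offset, s=self.sigma, scale=math.exp(self.mu)
        )


def lognormal_calibration(
    min_age: float, tail_span: float = 15.0, sigma: float = 1.0
) -> CalibrationPrior:
    """Lognormal calibration prior whose 95% quantile sits ``tail_span`` Myr
    above the fossil's minimum age.

    Solves ``offset + exp(mu + z_0.95 * sigma) = min_age + tail_span`` for mu,
    with sigma chosen by the user (the tail constraint alone cannot fix both
    log-scale parameters).
    """
    if min_age < 0 or tail_span <= 0 or sigma <= 0:
        raise ValueError("min_age >= 0, tail_span > 0 and sigma > 0 required")
    z95 = stats.norm.ppf(0.95)
    mu = math.log(tail_span) - z95 * sigma
    return CalibrationPrior(offset=min_age, mu=mu, sigma=sigma, tail_span=tail_span)
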