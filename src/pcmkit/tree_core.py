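"""Tree representation, Newick I/O, phylogenetic covariance and branch-length transforms.

The central object is :class:`Tree`, a light rooted-tree structure with
non-negative branch lengths, plus :class:`CovMatrix`, the expected trait
covariance among tips under Brownian motion (and its transformed variants).
All trait-evolution likelihoods in :mod:`pcmkit.trait_models` and the PGLS
machinery in :mod:`pcmkit.pgls_regression` consume these two types.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "Node",
    "CovMatrix",
    "NewickError",
    "TreeError",
    "parse_newick",
    "read_newick",
    "vcv",
    "transform_lambda",
    "transform_kappa",
    "transform_delta",
    "ou_covariance",
    "eb_covariance",
    "trend_covariance",
    "align_tree_and_traits",
    "read_trait_table",
]

#: floor applied to zero-length terminal branches so C stays invertible
DEFAULT_BRANCH_FLOOR = 1e-8


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate labels, ...)."""


class TreeError(ValueError):
    """Structural violation of the Tree invariants."""


class Node:
    """A single tree node. ``length`` is the branch above the node (0 for root)."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class Tree:
    """Rooted phylogeny with branch lengths in substitutions/site.

    Invariants (enforced on construction): exactly one root, unique tip
    labels, branch lengths finite and >= 0. Polytomies are permitted.
    Tip order is the left-to-right order of appearance and is the canonical
    ordering for every vector/matrix derived from the tree.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return parse_newick(text)

    # -- invariants ----------------------------------------------------

    def _validate(self) -> None:
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")
        seen: set[str] = set()
        for node in self.iter_nodes():
            if not math.isfinite(node.length) or node.length < 0:
                raise TreeError(
                    f"branch length {node.length!r} above {node.label!r} "
                    "is negative or non-finite"
                )
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabeled tip")
                if node.label in seen:
                    raise NewickError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)

    # -- traversal -----------------------------------------------------

    def iter_nodes(self) -> Iterable[Node]:
        """Preorder traversal (root first)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in canonical tip order."""
        depths = []
        stack = [(self.root, 0.0)]
        while stack:
            node, above = stack.pop()
            d = above + (node.length if node.parent is not None else 0.0)
            if node.is_leaf:
                depths.append(d)
            else:
                stack.extend((c, d) for c in reversed(node.children))
        # stack-based preorder with reversed children == canonical tip order
        return np.asarray(depths, dtype=float)

    def max_depth(self) -> float:
        return float(self.tip_depths().max())

    # -- manipulation --------------------------------------------------

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.length)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return Tree(rec(self.root), validate=False)

    def prune_to(self, keep: Sequence[str]) -> "Tree":
        """Restrict to the given tip labels, merging resulting degree-2 nodes.

        Branch lengths of merged unary chains are summed so patristic
        distances among kept tips are preserved exactly.
        """
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)[:5]}")

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                if node.label in keep_set:
                    return Node(node.label, node.length)
                return None
            kept_children = [c for c in (rec(ch) for ch in node.children) if c]
            if not kept_children:
                return None
            if len(kept_children) == 1:
                child = kept_children[0]
                child.length += node.length
                return child
            clone = Node(node.label, node.length)
            for c in kept_children:
                clone.add_child(c)
            return clone

        new_root = rec(self.root)
        if new_root is None:
            raise TreeError("pruning removed every tip")
        if new_root.is_leaf:
            raise TreeError("pruning left a single tip; no tree remains")
        new_root.length = 0.0
        return Tree(new_root)

    def apply_branch_floor(self, floor: float = DEFAULT_BRANCH_FLOOR) -> int:
        """Raise zero-length terminal branches to ``floor``; returns count."""
        n = 0
        for node in self.iter_nodes():
            if node.is_leaf and node.parent is not None and node.length < floor:
                node.length = floor
                n += 1
        if n:
            logger.info("applied branch floor %g to %d terminal branches", floor, n)
        return n

    # -- serialization -------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        out = io.StringIO()

        def needs_quotes(label: str) -> bool:
            return any(c in label for c in " ()[]{}:;,'\"")

        def write(node: Node) -> None:
            if node.children:
                out.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(child)
                out.write(")")
            if node.label:
                lab = node.label
                out.write(f"'{lab}'" if needs_quotes(lab) else lab)
            if node.parent is not None:
                out.write(f":{node.length:.{precision}g}")

        write(self.root)
        out.write(";")
        return out.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {self.n_tips} tips>"


@dataclass
class CovMatrix:
    """Expected among-tip trait covariance: ordered taxa plus an n x n matrix.

    ``values[i, j]`` is in branch-length units for the plain BM matrix, or
    squared-trait units once multiplied by a rate. Rows/columns follow
    ``taxa`` order.
    """

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def is_psd(self, tol: float = 1e-8) -> bool:
        eigvals = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        return bool(eigvals.min() >= -tol * max(1.0, eigvals.max()))

    def reorder(self, taxa: Sequence[str]) -> "CovMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CovMatrix(tuple(taxa), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Branch lengths are taken exactly as written; unlabeled internal nodes are
    left unlabeled; polytomies are preserved. Raises :class:`NewickError` on
    unbalanced parentheses, duplicate tip labels or negative branch lengths.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick statement must end with ';'")
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise NewickError(
                f"negative branch length {length} above {label or 'internal node'!r}"
            )
        node = Node(label, length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    try:
        return Tree(root)
    except TreeError as exc:
        raise NewickError(str(exc)) from exc


def read_newick(path: str) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def _clade_blocks(tree: Tree) -> tuple[list[str], list[tuple[float, np.ndarray]]]:
    """Return canonical tip labels and (branch_length, tip-index-array) blocks.

    Every non-root node contributes its branch length to the covariance of
    all tip pairs below it; summing the blocks yields the BM matrix. The
    block list is also the fast path for kappa transforms, which only change
    the lengths, not the blocks.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    blocks: list[tuple[float, np.ndarray]] = []

    def rec(node: Node) -> list[int]:
        if node.is_leaf:
            under = [index[node.label]]
        else:
            under = []
            for child in node.children:
                under.extend(rec(child))
        if node.parent is not None:
            blocks.append((node.length, np.asarray(under, dtype=np.intp)))
        return under

    rec(tree.root)
    return labels, blocks


def vcv(tree: Tree) -> CovMatrix:
    """Brownian-motion covariance: C_ij = root-to-MRCA(i, j) path length.

    The diagonal holds root-to-tip distances. Any branch attached above the
    root is ignored (it is shared by all tips and carries no information
    about their covariance structure relative to the root state).
    """
    labels, blocks = _clade_blocks(tree)
    n = len(labels)
    if n < 2:
        raise TreeError("need at least two tips for a covariance matrix")
    C = np.zeros((n, n))
    for length, idx in blocks:
        C[np.ix_(idx, idx)] += length
    return CovMatrix(tuple(labels), C)


def vcv_from_blocks(
    labels: Sequence[str], blocks: list[tuple[float, np.ndarray]], kappa: float = 1.0
) -> CovMatrix:
    """Rebuild the BM matrix from precomputed clade blocks, optionally with
    each branch length raised to ``kappa`` (0**kappa == 0; kappa==0 maps
    positive lengths to 1)."""
    n = len(labels)
    C = np.zeros((n, n))
    for length, idx in blocks:
        b = _kappa_branch(length, kappa)
        if b:
            C[np.ix_(idx, idx)] += b
    return CovMatrix(tuple(labels), C)


def _kappa_branch(b: float, kappa: float) -> float:
    if b == 0.0:
        return 0.0
    if kappa == 0.0:
        return 1.0
    return b**kappa


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform_lambda(C: CovMatrix, lam: float, lam_max: float = 1.0) -> CovMatrix:
    """Pagel's lambda: multiply off-diagonal covariances by ``lam``."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam > lam_max:
        raise ValueError(f"lambda {lam} exceeds lam_max {lam_max}")
    V = C.values * lam
    np.fill_diagonal(V, C.values.diagonal())
    return CovMatrix(C.taxa, V)


def transform_kappa(tree: Tree, kappa: float) -> Tree:
    """Raise every branch length to the power ``kappa``.

    ``0**kappa`` is defined as 0; ``kappa == 0`` maps every positive branch
    to 1 (punctuational clock).
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    out = tree.copy()
    for node in out.iter_nodes():
        if node.parent is not None:
            node.length = _kappa_branch(node.length, kappa)
    return out


def transform_delta(C: CovMatrix, delta: float, delta_max: float = 3.0) -> CovMatrix:
    """Raise each covariance entry to the power ``delta`` (0 stays 0).

    delta > 1 concentrates trait change late in the tree, delta < 1 early.
    The domain is capped at ``delta_max`` (3 by convention).
    """
    if not 0 < delta <= delta_max:
        raise ValueError(f"delta must be in (0, {delta_max}], got {delta}")
    return CovMatrix(C.taxa, np.power(C.values, delta))


def ou_covariance(tree: Tree, alpha: float, sigma2: float) -> CovMatrix:
    """Stationary Ornstein-Uhlenbeck covariance on a (possibly
    non-ultrametric) tree.

    V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij))
    with s_ij the root-to-MRCA path length and d_ij the patristic distance
    between tips i and j.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    C = vcv(tree)
    s = C.values
    h = s.diagonal()
    d = h[:, None] + h[None, :] - 2.0 * s
    V = sigma2 / (2.0 * alpha) * np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * s))
    return CovMatrix(C.taxa, V)


def eb_covariance(tree: Tree, a: float, sigma2: float) -> CovMatrix:
    """Early-burst covariance: rate sigma2 * exp(a t) decaying from the root.

    A branch segment [t1, t2] contributes sigma2 * (exp(a t2) - exp(a t1))/a,
    so the shared-path sum collapses to sigma2 * (exp(a s_ij) - 1)/a; a == 0
    reduces exactly to Brownian motion.
    """
    if a > 0:
        raise ValueError(f"early-burst exponent must be <= 0, got {a}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    C = vcv(tree)
    if a == 0:
        return CovMatrix(C.taxa, sigma2 * C.values)
    V = sigma2 * np.expm1(a * C.values) / a
    return CovMatrix(C.taxa, V)


def trend_covariance(tree: Tree, sigma0_2: float, slope: float) -> CovMatrix:
    """Time-trend diffusion covariance: instantaneous rate sigma0_2 + slope*t.

    V_ij = sigma0_2 * s_ij + slope * s_ij**2 / 2, where s_ij is the shared
    root path. The rate integral must stay positive along every root path.
    """
    C = vcv(tree)
    s = C.values
    V = sigma0_2 * s + 0.5 * slope * s * s
    if np.any(V.diagonal() <= 0):
        raise ValueError(
            "trend parameters give non-positive variance on some root path"
        )
    return CovMatrix(C.taxa, V)


# ---------------------------------------------------------------------------
# Trait alignment
# ---------------------------------------------------------------------------

def read_trait_table(path: str) -> pd.DataFrame:
    """Read a TSV trait table; the first column is the tip label (index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def align_tree_and_traits(
    tree: Tree,
    traits: pd.DataFrame | pd.Series,
    column: str | None = None,
    branch_floor: float = DEFAULT_BRANCH_FLOOR,
) -> tuple[Tree, np.ndarray]:
    """Prune tree and trait column to their shared tips.

    Tips lacking the trait (absent from the table, or NaN) are pruned with
    branch-length merging; the returned vector follows the pruned tree's
    canonical tip order. Requires >= 3 overlapping tips.
    """
    if isinstance(traits, pd.DataFrame):
        if column is None:
            raise ValueError("column required when passing a DataFrame")
        if column not in traits.columns:
            raise KeyError(f"trait column {column!r} not in table")
        series = traits[column]
    else:
        series = traits
    series = series.dropna()
    tips = tree.tip_labels
    shared = [t for t in tips if t in series.index]
    if len(shared) < 3:
        raise TreeError(
            f"only {len(shared)} tips overlap between tree and trait column; "
            "need >= 3 to fit any model"
        )
    dropped = sorted(set(tips) - set(shared))
    if dropped:
        logger.info("dropping %d tips without trait values", len(dropped))
        pruned = tree.prune_to(shared)
    else:
        pruned = tree.copy()
    pruned.apply_branch_floor(branch_floor)
    y = series.loc[pruned.tip_labels].to_numpy(dtype=float)
    return pruned, y
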