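"""Phylogenetic tree handling: parsing, branch identity, root-to-tip paths,
and the Brownian-motion variance–covariance matrix with Pagel's λ transform.

Branches are identified by the label of their *child* node.  Internal nodes
without a label in the input receive deterministic labels ``N<k>`` where ``k``
is the node's 1-based index among unlabeled internal nodes in post-order
traversal, so that branch-rate tables and trees can be joined reproducibly.

Trees are assumed ultrametric (a time-calibrated chronogram); violation of
ultrametricity is reported as a warning, not an error, because downstream
generalized least squares remains well defined and real chronogram exports
carry rounding error.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (
    NewickParseError,
    TreeStructureError,
    UltrametricityWarning,
    UnknownSpeciesError,
)

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "parse_newick",
    "root_to_tip_path",
    "vcv_matrix",
    "lambda_transform",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths, indexed by node label.

    ``parent[label]`` is ``None`` for the root; ``branch_length[label]`` is the
    length of the branch above ``label`` (absent for the root).  Children are
    kept in input order so serialization is deterministic.
    """

    root: str
    parent: dict[str, str | None]
    children: dict[str, list[str]]
    branch_length: dict[str, float]
    _depths: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def tips(self) -> list[str]:
        return [n for n in self._postorder() if not self.children[n]]

    @property
    def internal_nodes(self) -> list[str]:
        return [n for n in self._postorder() if self.children[n]]

    def _postorder(self) -> list[str]:
        out: list[str] = []

        def visit(n: str) -> None:
            for c in self.children[n]:
                visit(c)
            out.append(n)

        visit(self.root)
        return out

    def node_depth(self, label: str) -> float:
        """Summed branch length from the root down to ``label``."""
        if label not in self.parent:
            raise UnknownSpeciesError(label)
        if not self._depths:
            self._depths[self.root] = 0.0
            for n in reversed(self._postorder()):  # pre-order
                for c in self.children[n]:
                    self._depths[c] = self._depths[n] + self.branch_length[c]
        return self._depths[label]

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return max(self.node_depth(t) for t in self.tips)

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = [self.node_depth(t) for t in self.tips]
        h = max(depths)
        return all(abs(d - h) <= rtol * max(h, 1.0) for d in depths)

    def ancestors(self, label: str) -> list[str]:
        """Nodes from the root to ``label`` inclusive."""
        if label not in self.parent:
            raise UnknownSpeciesError(label)
        chain = [label]
        while self.parent[chain[-1]] is not None:
            chain.append(self.parent[chain[-1]])  # type: ignore[arg-type]
        return chain[::-1]

    def mrca(self, a: str, b: str) -> str:
        pa, pb = self.ancestors(a), self.ancestors(b)
        last = pa[0]
        for x, y in zip(pa, pb):
            if x != y:
                break
            last = x
        return last

    def to_newick(self) -> str:
        def fmt(n: str) -> str:
            label = "" if not self.children[n] else n
            if not self.children[n]:
                label = n
            inner = ""
            if self.children[n]:
                inner = "(" + ",".join(fmt(c) for c in self.children[n]) + ")"
            bl = ""
            if self.parent[n] is not None:
                bl = f":{self.branch_length[n]:.10g}"
            return f"{inner}{label}{bl}"

        return fmt(self.root) + ";"

    def subtree_species_check(self, species: list[str]) -> None:
        tipset = set(self.tips)
        missing = [s for s in species if s not in tipset]
        if missing:
            raise UnknownSpeciesError(f"species not in tree: {missing}")


@dataclass
class PhyloCovariance:
    """Brownian-motion variance–covariance matrix over a set of tips.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of species ``i``
    and ``j`` (time units); the diagonal holds root-to-tip distances, equal to
    the tree height for an ultrametric tree.
    """

    species: list[str]
    matrix: np.ndarray
    tree_height: float

    def restrict(self, subset: list[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in subset]
        return PhyloCovariance(list(subset), self.matrix[np.ix_(idx, idx)], self.tree_height)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required on every non-root edge and must be strictly
    positive and finite.  Unlabeled internal nodes receive deterministic
    post-order labels ``N<k>``.  Non-ultrametric path sums trigger an
    :class:`~phylorates.errors.UltrametricityWarning`.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    # Assign deterministic labels to unlabeled internal nodes (post-order).
    k = 0
    used = set()
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickParseError("tip without a label")
            used.add(nd.taxon.label)
    for nd in dt.postorder_node_iter():
        if not nd.is_leaf():
            if nd.label is None or nd.label == "":
                k += 1
                lab = f"N{k}"
                while lab in used:
                    k += 1
                    lab = f"N{k}"
                nd.label = lab
            used.add(nd.label)

    root = dt.seed_node
    parent: dict[str, str | None] = {}
    children: dict[str, list[str]] = {}
    branch_length: dict[str, float] = {}
    tips_seen: set[str] = set()

    def label_of(nd: dendropy.Node) -> str:
        return nd.taxon.label if nd.is_leaf() else nd.label  # type: ignore[return-value]

    def build(nd: dendropy.Node, par: str | None) -> None:
        lab = label_of(nd)
        if lab in parent:
            raise TreeStructureError(f"duplicate node label: {lab!r}")
        if nd.is_leaf():
            if lab in tips_seen:
                raise TreeStructureError(f"duplicate tip label: {lab!r}")
            tips_seen.add(lab)
        parent[lab] = par
        children[lab] = []
        if par is not None:
            bl = nd.edge.length
            if bl is None:
                raise NewickParseError(f"missing branch length above node {lab!r}")
            bl = float(bl)
            if not np.isfinite(bl) or bl <= 0:
                raise TreeStructureError(
                    f"branch length above node {lab!r} must be strictly positive, got {bl}"
                )
            branch_length[lab] = bl
            children[par].append(lab)
        for ch in nd.child_nodes():
            build(ch, lab)

    build(root, None)
    tree = PhyloTree(root=label_of(root), parent=parent, children=children,
                     branch_length=branch_length)
    if len(tree.tips) < 2:
        raise TreeStructureError("tree must have at least two tips")
    if not tree.is_ultrametric():
        depths = sorted(tree.node_depth(t) for t in tree.tips)
        warnings.warn(
            f"tree is not ultrametric: root-to-tip path sums range "
            f"{depths[0]:.6g} to {depths[-1]:.6g}",
            UltrametricityWarning,
            stacklevel=2,
        )
    return tree


def root_to_tip_path(tree: PhyloTree, tip: str) -> list[str]:
    """Branch ids (child-node labels) on the path from the root to ``tip``,
    in root→tip order."""
    if tip not in tree.parent or tree.children[tip]:
        raise UnknownSpeciesError(f"unknown tip: {tip!r}")
    return tree.ancestors(tip)[1:]


def vcv_matrix(tree: PhyloTree, species: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance of tip values: ``C[i, j]`` is the depth of
    the most recent common ancestor of tips ``i`` and ``j``."""
    if species is None:
        species = tree.tips
    species = list(species)
    if len(species) < 2:
        raise TreeStructureError("need at least two species for a covariance matrix")
    tree.subtree_species_check(species)
    n = len(species)
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        C[i, i] = tree.node_depth(a)
        for j in range(i + 1, n):
            d = tree.node_depth(tree.mrca(a, species[j]))
            C[i, j] = C[j, i] = d
    return PhyloCovariance(species, C, tree.height)


def lambda_transform(C: PhyloCovariance | np.ndarray, lam: float) -> np.ndarray:
    """Pagel's λ transform: multiply off-diagonal covariances by ``lam``.

    λ=1 returns the Brownian matrix unchanged; λ=0 removes all phylogenetic
    covariance (an ordinary-least-squares error structure).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    out = M * lam
    np.fill_diagonal(out, np.diag(M))
    return out
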