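"""Chronogram I/O and age/LTT machinery.

A chronogram is a rooted tree whose branch lengths are absolute time in
millions of years (Myr), so that node heights are divergence ages in Ma
before present (present = 0).  Everything downstream — ancestral-area
likelihoods, birth–death shift detection, interval diversification rates —
consumes this one container.

Conventions
-----------
* Ages are Ma before present; branch lengths are Myr.  The conversion
  between a node's depth (root-to-node path length) and its age is always
  explicit: ``age = root_age - depth``.
* Ultrametricity is enforced within a relative tolerance of the root age
  (default 1e-6).  Operations that use branch lengths (ages, LTT,
  truncation, diversification) reject non-ultrametric trees; parsimony
  operations only need the topology and merely warn.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "LTTCurve",
    "NewickError",
    "parse_newick",
    "ltt",
    "prune_to_taxa",
    "truncate_at_age",
    "branching_times",
]

DEFAULT_ULTRAMETRIC_TOL = 1e-6


class NewickError(ValueError):
    """Malformed Newick input or invalid tree structure."""


@dataclass
class LTTCurve:
    """Lineage-through-time curve of a reconstructed tree.

    ``ages`` are event ages in Ma, strictly decreasing toward 0;
    ``counts[i]`` is the number of lineages alive on the age interval just
    *younger* than ``ages[i]`` (i.e. after the branching events at that
    age).  The final entry is age 0 with the tip count.
    """

    ages: np.ndarray
    counts: np.ndarray

    def count_at(self, age: float) -> int:
        """Number of lineages alive at ``age`` (1 above the root)."""
        if age >= self.ages[0]:
            return 1
        idx = np.searchsorted(-self.ages, -age, side="left")
        # ages[idx-1] > age >= ages[idx]; lineage count after event idx-1
        return int(self.counts[min(idx, len(self.counts) - 1) - 1]) if idx > 0 else 1


class Chronogram:
    """Rooted tree with branch lengths in Myr, wrapped around dendropy.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``; consumed, not copied.
    require_ultrametric:
        Reject trees whose root-to-tip depths differ by more than
        ``tol * root_age``.  Parsimony-only callers pass False.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        require_ultrametric: bool = True,
        tol: float = DEFAULT_ULTRAMETRIC_TOL,
    ):
        self._tree = tree
        self.tol = tol
        self._validate(require_ultrametric)
        self._ages: dict | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        text: str,
        require_ultrametric: bool = True,
        tol: float = DEFAULT_ULTRAMETRIC_TOL,
    ) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parser classes
            offset = getattr(getattr(exc, "token", None), "column", None)
            loc = f" near character {offset}" if offset is not None else ""
            raise NewickError(f"malformed Newick string{loc}: {exc}") from exc
        tree.is_rooted = True
        return cls(tree, require_ultrametric=require_ultrametric, tol=tol)

    def _validate(self, require_ultrametric: bool) -> None:
        t = self._tree
        if t.seed_node is None or len(t.seed_node.child_nodes()) == 0:
            raise NewickError("empty tree")
        labels = []
        for node in t.preorder_node_iter():
            if node is not t.seed_node:
                if node.edge.length is None:
                    raise NewickError(
                        f"missing branch length on edge above "
                        f"{node.taxon.label if node.taxon else 'an internal node'}"
                    )
                if node.edge.length < 0:
                    raise NewickError("negative branch length")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickError("unlabelled tip")
                labels.append(node.taxon.label)
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        depths = self._tip_depths()
        root_age = max(depths.values())
        if root_age <= 0:
            raise NewickError("tree has zero depth")
        spread = root_age - min(depths.values())
        if spread > self.tol * root_age:
            worst_lo = min(depths, key=depths.get)
            worst_hi = max(depths, key=depths.get)
            msg = (
                f"tree is not ultrametric: tip depths differ by {spread:.6g} Myr "
                f"(worst pair: {worst_lo} at {depths[worst_lo]:.6g}, "
                f"{worst_hi} at {depths[worst_hi]:.6g})"
            )
            if require_ultrametric:
                raise NewickError(msg)
            warnings.warn(msg)

    def _tip_depths(self) -> dict:
        depths = {}
        stack = [(self._tree.seed_node, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf():
                depths[node.taxon.label] = d
            for c in node.child_nodes():
                stack.append((c, d + c.edge.length))
        return depths

    # -- basic accessors ----------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def root_age(self) -> float:
        return max(self._tip_depths().values())

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def node_ages(self) -> dict:
        """Map dendropy node -> age in Ma (tips clipped to exactly 0)."""
        if self._ages is not None:
            return self._ages
        root_age = self.root_age
        ages = {}
        stack = [(self._tree.seed_node, 0.0)]
        while stack:
            node, d = stack.pop()
            ages[node] = 0.0 if node.is_leaf() else root_age - d
            for c in node.child_nodes():
                stack.append((c, d + c.edge.length))
        self._ages = ages
        return ages

    def internal_node_ages(self) -> np.ndarray:
        """Ages of internal nodes, descending (root first)."""
        ages = self.node_ages()
        vals = sorted(
            (ages[n] for n in self._tree.preorder_internal_node_iter()),
            reverse=True,
        )
        return np.asarray(vals)

    # -- output -------------------------------------------------------

    def newick(self) -> str:
        """Newick string with branch lengths at full double precision."""
        out = io.StringIO()
        self._write_node(self._tree.seed_node, out)
        out.write(";")
        return out.getvalue()

    def _write_node(self, node, out) -> None:
        children = node.child_nodes()
        if children:
            out.write("(")
            for i, c in enumerate(children):
                if i:
                    out.write(",")
                self._write_node(c, out)
            out.write(")")
            if node.label:
                out.write(str(node.label))
        else:
            out.write(node.taxon.label.replace(" ", "_"))
        if node.parent_node is not None:
            out.write(f":{node.edge.length!r}")

    def clone(self) -> "Chronogram":
        return Chronogram(
            self._tree.clone(depth=1), require_ultrametric=False, tol=self.tol
        )

    def __repr__(self) -> str:
        return f"<Chronogram n_tips={self.n_tips} root_age={self.root_age:.4g} Ma>"


def parse_newick(
    text: str,
    require_ultrametric: bool = True,
    tol: float = DEFAULT_ULTRAMETRIC_TOL,
) -> Chronogram:
    """Parse a Newick string into a :class:`Chronogram`."""
    return Chronogram.from_newick(text, require_ultrametric=require_ultrametric, tol=tol)


def ltt(tree: Chronogram) -> LTTCurve:
    """Lineage-through-time curve of a reconstructed (extant-tip) tree."""
    ages = tree.internal_node_ages()
    # merge coincident event ages
    uniq, counts_at = [], []
    k = 1
    for a in ages:
        k += 1
        if uniq and abs(uniq[-1] - a) < 1e-12:
            counts_at[-1] = k
        else:
            uniq.append(a)
            counts_at.append(k)
    uniq.append(0.0)
    counts_at.append(counts_at[-1])
    return LTTCurve(ages=np.asarray(uniq), counts=np.asarray(counts_at))


def prune_to_taxa(tree: Chronogram, keep) -> Chronogram:
    """Subtree induced by ``keep``, with degree-2 nodes suppressed.

    Retained tips keep their original root-to-tip depth, so the result is
    ultrametric with (possibly) a younger root.
    """
    keep = set(keep)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    sub = tree.dendropy_tree.clone(depth=1)
    sub.retain_taxa_with_labels(list(keep))
    # drop a dangling root edge left by pruning so depth starts at the MRCA
    sub.seed_node.edge.length = None
    return Chronogram(sub, require_ultrametric=True, tol=tree.tol)


def truncate_at_age(tree: Chronogram, cutoff: float) -> Chronogram:
    """Cut the tree at ``cutoff`` Ma, dropping all younger branching events.

    Each lineage alive at the cutoff becomes a single tip ending exactly at
    the cutoff line, so the returned tree's tip count equals the LTT count
    at ``cutoff`` and its root age (measured from its own tips) is
    ``root_age - cutoff``.  Absolute ages are recovered by adding
    ``cutoff``, stored on the result as ``age_offset``.
    """
    if not 0 < cutoff < tree.root_age:
        raise ValueError(
            f"cutoff must lie in (0, root age={tree.root_age:.4g}); got {cutoff}"
        )
    t = tree.dendropy_tree.clone(depth=1)
    chrono = Chronogram(t, require_ultrametric=True, tol=tree.tol)
    ages = chrono.node_ages()
    counter = 0
    for node in list(t.preorder_node_iter()):
        if node.parent_node is None:
            continue
        parent_age = ages[node.parent_node]
        node_age = ages[node]
        if parent_age > cutoff >= node_age:
            # lineage crosses the cutoff: clip it to a tip on the line
            node.edge.length = parent_age - cutoff
            if not node.is_leaf():
                node.clear_child_nodes()
                counter += 1
                node.taxon = t.taxon_namespace.new_taxon(f"trunc_{counter}")
    result = Chronogram(t, require_ultrametric=True, tol=tree.tol)
    result.age_offset = cutoff
    return result


def branching_times(tree: Chronogram) -> np.ndarray:
    """Internal node ages of a binary tree, descending (n-1 for n tips)."""
    if not tree.is_binary():
        raise ValueError("tree contains polytomies; branching times need a binary tree")
    return tree.internal_node_ages()
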