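"""Rooted population phylogenies and their branch partitions.

Every branch of a rooted tree splits the populations (leaves) into a
*descendant set* (below the branch) and an *ancestral set* (everything
else).  The differentiation machinery works entirely on these partitions;
branch lengths are never used.

Branch identifiers are the sorted descendant leaf labels joined with ``|``,
which makes them stable across parsers, node orderings and reruns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy

__all__ = ["Branch", "PopulationTree"]


@dataclass(frozen=True)
class Branch:
    """One branch (edge) of a rooted population tree."""

    id: str
    descendants: frozenset[str]
    parent: str | None  # id of the parent branch, None for children of the root

    def __repr__(self) -> str:  # keep test output readable on big trees
        return f"Branch({self.id!r}, n_desc={len(self.descendants)})"


def _branch_id(leaves: frozenset[str]) -> str:
    return "|".join(sorted(leaves))


class PopulationTree:
    """Rooted population phylogeny with per-branch ancestral/descendant sets.

    A rooted binary tree with ``n`` leaves has ``2n - 2`` branches (the root
    itself has no branch).  The two children of the root induce complementary
    partitions of the leaf set; both are listed in :attr:`branches`, and the
    testing layer suppresses one of them (see
    :meth:`tested_branches`).
    """

    def __init__(self, tree: dendropy.Tree, allow_resolve: bool = False):
        root = tree.seed_node
        n_root_children = len(root.child_nodes())
        if n_root_children != 2:
            if not allow_resolve:
                raise ValueError(
                    f"tree root has {n_root_children} children; a rooted "
                    "bifurcating tree is required (pass allow_resolve=True "
                    "to resolve the root arbitrarily)"
                )
            tree.resolve_polytomies()
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf names must be unique")
        self.leaves: list[str] = sorted(leaves)
        self._leafset = frozenset(self.leaves)

        branches: list[Branch] = []
        children: dict[str, list[str]] = {}
        clade: dict[int, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                clade[id(node)] = frozenset([node.taxon.label])
            else:
                cl: frozenset[str] = frozenset()
                for ch in node.child_nodes():
                    cl |= clade[id(ch)]
                clade[id(node)] = cl
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            parent = node.parent_node
            pid = None if parent is root else _branch_id(clade[id(parent)])
            bid = _branch_id(clade[id(node)])
            branches.append(Branch(bid, clade[id(node)], pid))
            if pid is not None:
                children.setdefault(pid, []).append(bid)
        # deterministic order: by size then id
        branches.sort(key=lambda b: (len(b.descendants), b.id))
        self.branches: list[Branch] = branches
        self._by_id = {b.id: b for b in branches}
        self._children = children
        # strict descendant closure per branch
        self._below: dict[str, frozenset[str]] = {}
        for b in branches:  # sorted by clade size, so children come first
            below: set[str] = set()
            for c in children.get(b.id, ()):
                below.add(c)
                below |= self._below[c]
            self._below[b.id] = frozenset(below)

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, allow_resolve: bool = False) -> "PopulationTree":
        """Parse a rooted Newick tree from a string or file path."""
        if "(" in source:
            stream = io.StringIO(source)
            tree = dendropy.Tree.get(file=stream, schema="newick", rooting="force-rooted")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick", rooting="force-rooted")
        return cls(tree, allow_resolve=allow_resolve)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # ------------------------------------------------------------------
    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch(self, branch_id: str) -> Branch:
        try:
            return self._by_id[branch_id]
        except KeyError:
            raise KeyError(f"no branch {branch_id!r} in tree") from None

    def __contains__(self, branch_id: str) -> bool:
        return branch_id in self._by_id

    def ancestral_set(self, branch_id: str) -> frozenset[str]:
        """Populations above the branch (complement of the descendant set)."""
        return self._leafset - self._by_id[branch_id].descendants

    def descendant_branches(self, branch_id: str) -> frozenset[str]:
        """Branch ids strictly below ``branch_id``."""
        return self._below[branch_id]

    def is_descendant(self, branch_id: str, of: str) -> bool:
        """True if ``branch_id`` lies strictly below branch ``of``."""
        return branch_id in self._below[of]

    def root_child_ids(self) -> list[str]:
        return sorted(b.id for b in self.branches if b.parent is None)

    def tested_branches(self) -> list[Branch]:
        """Branches entering the differentiation test.

        The two children of the root carry the same information (their
        partitions are complements, so their deviations are sign flips of
        one another); the one with the lexicographically larger id is
        suppressed to avoid double counting.
        """
        rc = self.root_child_ids()
        drop = rc[-1] if len(rc) == 2 else None
        return [b for b in self.branches if b.id != drop]

    def validate_populations(self, populations: set[str]) -> None:
        """Check leaves map 1-1 onto the genotype population labels."""
        missing = sorted(self._leafset - populations)
        if missing:
            raise ValueError(
                "tree leaves absent from genotype populations: " + ", ".join(missing)
            )
        extra = sorted(populations - self._leafset)
        if extra:
            raise ValueError(
                "genotype populations absent from tree: " + ", ".join(extra)
            )
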