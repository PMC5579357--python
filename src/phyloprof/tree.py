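"""Rooted species trees (topology only), backed by dendropy.

The species tree is the substrate for Dollo parsimony: only the rooted
topology matters, branch lengths are ignored.  Leaves are labeled with the
4-letter species codes of the catalog; soft polytomies are preserved as-is.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import dendropy

from .profiles import SpeciesCatalog


class SpeciesTree:
    """Thin wrapper around a rooted :class:`dendropy.Tree`.

    Precomputes, for every node, the frozen set of leaf codes below it (its
    *clade*), which is the stable identity used for origins and loss branches
    throughout the package.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise ValueError("tree has no root")
        self._tree = tree
        self._clades: dict[dendropy.Node, frozenset[str]] = {}
        codes: list[str] = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if not label:
                    raise ValueError("tree contains an unlabeled leaf")
                self._clades[node] = frozenset([label])
            else:
                clade: frozenset[str] = frozenset()
                for child in node.child_nodes():
                    clade |= self._clades[child]
                self._clades[node] = clade
        # left-to-right (newick) leaf order
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                codes.append(next(iter(self._clades[node])))
        if len(codes) != len(set(codes)):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dupes}")
        self._leaf_codes = tuple(codes)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        if tree.is_rooted is False:
            raise ValueError(
                "tree is explicitly unrooted ([&U]); root it before use"
            )
        tree.is_rooted = True
        return cls(tree)

    # -- basic accessors ---------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def leaf_codes(self) -> tuple[str, ...]:
        """Leaves in left-to-right newick order (reflects relatedness)."""
        return self._leaf_codes

    def __len__(self) -> int:
        return len(self._leaf_codes)

    def nodes(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def internal_nodes(self) -> list[dendropy.Node]:
        return [n for n in self.nodes() if not n.is_leaf()]

    def children(self, node: dendropy.Node) -> list[dendropy.Node]:
        return node.child_nodes()

    def clade(self, node: dendropy.Node) -> frozenset[str]:
        """Set of leaf codes under ``node`` (a leaf's clade is itself)."""
        return self._clades[node]

    def node_for_clade(self, clade: frozenset[str]) -> dendropy.Node:
        for node, c in self._clades.items():
            if c == clade:
                return node
        raise KeyError(f"no node with clade {sorted(clade)}")

    def mrca(self, codes: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a non-empty set of leaf codes."""
        target = frozenset(codes)
        if not target:
            raise ValueError("mrca of an empty code set is undefined")
        unknown = target - self._clades[self.root]
        if unknown:
            raise KeyError(f"codes not in tree: {sorted(unknown)}")
        node = self.root
        while True:
            for child in node.child_nodes():
                if target <= self._clades[child]:
                    node = child
                    break
            else:
                return node

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def catalog(self) -> SpeciesCatalog:
        """Catalog whose order is this tree's leaf order."""
        return SpeciesCatalog(self._leaf_codes)


def read_species_tree(path: str | Path, catalog: SpeciesCatalog) -> SpeciesTree:
    """Read a rooted newick tree and validate its leaves against ``catalog``."""
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"tree file {path} is empty")
    tree = SpeciesTree.from_newick(text)
    unknown = sorted(set(tree.leaf_codes) - set(catalog.codes))
    if unknown:
        raise ValueError(
            f"tree leaves not present in the species catalog: {unknown}"
        )
    return tree
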