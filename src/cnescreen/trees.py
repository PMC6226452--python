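"""Phylogeny container used throughout the screen.

A :class:`PhyloTree` wraps a dendropy tree (branch lengths in expected
substitutions per site) together with the two species annotations the
divergence screen needs: the trait-loss lineages and the close-relative
subset used for the local Z-score.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property

import dendropy
import numpy as np


@dataclass(frozen=True)
class PhyloTree:
    """A rooted phylogeny with trait-loss annotations.

    Parameters
    ----------
    newick_text:
        Newick string with branch lengths in substitutions/site.
    loss_species:
        Leaf labels of the trait-loss lineages (e.g. snakes for limb loss).
    local_comparison_species:
        Leaf labels of the close relatives used for the local Z-score
        (e.g. the lizards). May be empty if no local screen is run.
    """

    newick_text: str
    loss_species: tuple[str, ...] = ()
    local_comparison_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = self.species
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in tree")
        for group, name in (
            (self.loss_species, "loss_species"),
            (self.local_comparison_species, "local_comparison_species"),
        ):
            unknown = set(group) - set(labels)
            if unknown:
                raise ValueError(f"{name} not in tree: {sorted(unknown)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @cached_property
    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(
            data=self.newick_text, schema="newick", preserve_underscores=True
        )
        t.is_rooted = True
        return t

    @cached_property
    def species(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    @property
    def other_species(self) -> tuple[str, ...]:
        """All leaves that are not trait-loss lineages."""
        loss = set(self.loss_species)
        return tuple(s for s in self.species if s not in loss)

    @cached_property
    def distance_to_root(self) -> dict[str, float]:
        """Sum of branch lengths from each leaf up to the root.

        This is the "evolutionary distance to the ancestor" denominator of
        the normalized identity when the comparison ancestor is the root.
        """
        out: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def loss_exclusive_edges(self) -> list[dendropy.Edge]:
        """Edges whose entire leaf-descendant set lies within loss_species.

        These are the branches on which relaxation of purifying selection is
        modelled for relaxed CNEs.
        """
        loss = set(self.loss_species)
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            if leaves and leaves <= loss:
                out.append(node.edge)
        return out

    @cached_property
    def bm_covariance(self) -> "tuple[tuple[str, ...], np.ndarray]":
        """Brownian-motion covariance: shared root-to-MRCA path length.

        Returns the species order and the matrix; diagonal entries equal each
        leaf's root-to-tip distance.
        """
        order = self.species
        idx = {s: i for i, s in enumerate(order)}
        n = len(order)
        cov = np.zeros((n, n))
        # depth of every node from the root
        depth: dict[int, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depth[id(node)] = 0.0
            else:
                depth[id(node)] = depth[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
        # accumulate via postorder: each internal node is the MRCA of every
        # cross pair of its child clades
        leafsets: dict[int, list[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[id(node)] = [node.taxon.label]
                cov[idx[node.taxon.label], idx[node.taxon.label]] = depth[id(node)]
                continue
            children = [leafsets[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for sa in children[a]:
                        for sb in children[b]:
                            cov[idx[sa], idx[sb]] = d
                            cov[idx[sb], idx[sa]] = d
            leafsets[id(node)] = [s for ch in children for s in ch]
        return order, cov

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick_text.rstrip("\n") + "\n")

    @classmethod
    def from_newick_file(
        cls,
        path,
        loss_species: tuple[str, ...] = (),
        local_comparison_species: tuple[str, ...] = (),
    ) -> "PhyloTree":
        with open(path) as fh:
            text = fh.read().strip()
        return cls(text, tuple(loss_species), tuple(local_comparison_species))
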