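"""Phylogenetic correlation matrices from topology alone (Grafen).

A supplied Newick tree typically carries no divergence times, so branch
lengths are assigned following Grafen: each node's height is the number
of descendant tips minus one, heights are normalised by the root height
(tree depth 1, power parameter rho = 1), and the expected correlation of
two tips under Brownian motion is the shared root-to-MRCA path length,
i.e. 1 minus the normalised MRCA height.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = ["PhyloCorrelation", "grafen_correlation"]


def _normalise_name(name: str) -> str:
    return name.strip().replace("_", " ").casefold()


@dataclass(frozen=True)
class PhyloCorrelation:
    """Species-ordered dense correlation matrix (unit diagonal, PSD)."""

    species: tuple[str, ...]
    matrix: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


def grafen_correlation(
    newick_text: str,
    species: list[str] | None = None,
    allow_missing: bool = False,
) -> PhyloCorrelation:
    """Grafen correlation matrix for ``species`` from a Newick topology.

    Species are matched to tip labels after normalisation (underscores
    treated as spaces, case-folded).  Polytomies are accepted.  Species
    absent from the tree raise an error unless ``allow_missing`` is set,
    in which case they are treated as attached at the root (correlation
    zero with everything else).
    """
    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    tips = [leaf for leaf in tree.leaf_node_iter()]
    label_to_tip = {}
    for leaf in tips:
        label = leaf.taxon.label if leaf.taxon is not None else ""
        label_to_tip[_normalise_name(label)] = leaf
    if species is None:
        species = [
            leaf.taxon.label.replace(" ", "_") if leaf.taxon else ""
            for leaf in tips
        ]
    missing = [sp for sp in species if _normalise_name(sp) not in label_to_tip]
    if missing and not allow_missing:
        raise ValueError(f"species not found as tips: {missing}")

    n = len(species)
    placed = [sp for sp in species if sp not in set(missing)]
    # Grafen heights: tips 0, internal node = (#descendant tips) - 1.
    wanted = {id(label_to_tip[_normalise_name(sp)]): i
              for i, sp in enumerate(species) if sp in set(placed)}
    corr = np.eye(n)
    if len(placed) >= 2:
        root_height = None
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.grafen_tips = 1
                node.grafen_wanted = (
                    [wanted[id(node)]] if id(node) in wanted else []
                )
                continue
            child_tips = [c.grafen_tips for c in node.child_nodes()]
            node.grafen_tips = sum(child_tips)
            height = node.grafen_tips - 1
            child_sets = [c.grafen_wanted for c in node.child_nodes()]
            # pairs of requested tips whose MRCA is exactly this node
            for i, set_i in enumerate(child_sets):
                for set_j in child_sets[i + 1 :]:
                    for a in set_i:
                        for b in set_j:
                            corr[a, b] = corr[b, a] = height
            node.grafen_wanted = [x for s in child_sets for x in s]
            root_height = height
        if root_height and root_height > 0:
            off = ~np.eye(n, dtype=bool)
            corr[off] = 1.0 - corr[off] / root_height
        else:  # degenerate: all requested tips in a cherry-less tree
            corr[~np.eye(n, dtype=bool)] = 0.0
        # species allowed to be missing correlate with nothing
        for i, sp in enumerate(species):
            if sp in missing:
                corr[i, :] = 0.0
                corr[:, i] = 0.0
                corr[i, i] = 1.0
    return PhyloCorrelation(species=tuple(species), matrix=corr)
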