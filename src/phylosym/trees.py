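"""Host phylogenies and distance-matrix plumbing.

`HostTree` wraps a rooted dendropy tree with non-negative branch lengths and
normalized tip labels.  Patristic distances feed the Mantel battery; the
cluster-set helpers here are shared by the topology-congruence metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix


def normalize_label(label: str) -> str:
    """Canonical species label: underscores for spaces, case-folded."""
    return label.strip().replace(" ", "_").casefold()


@dataclass
class HostTree:
    """A rooted host phylogeny with branch lengths in time-like units."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in host tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "HostTree":
        kwargs = dict(schema="newick", preserve_underscores=True)
        try:
            if is_path:
                tree = dendropy.Tree.get(path=str(source), **kwargs)
            else:
                tree = dendropy.Tree.get(data=source, **kwargs)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"duplicate tip labels in newick: {err}") from err
        return cls(tree)

    def to_newick(self, path=None) -> str:
        s = self.tree.as_string(schema="newick", unquoted_underscores=True,
                                suppress_rooting=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def find_tips(self, species: list[str]) -> dict[str, str]:
        """Map requested species names to actual tip labels (normalized match)."""
        by_norm = {normalize_label(t): t for t in self.tip_labels}
        mapping, unknown = {}, []
        for sp in species:
            tip = by_norm.get(normalize_label(sp))
            if tip is None:
                unknown.append(sp)
            else:
                mapping[sp] = tip
        if unknown:
            raise KeyError(f"species not found among tree tips: {unknown}")
        return mapping

    def restrict_to(self, species: list[str]) -> "HostTree":
        """Prune to the given species (tips relabeled to the requested names)."""
        mapping = self.find_tips(species)
        tree = self.tree.clone(depth=1)
        keep = set(mapping.values())
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        rev = {v: k for k, v in mapping.items()}
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = rev[leaf.taxon.label]
        return HostTree(tree)


def patristic_distances(host: HostTree, species: list[str]) -> DistanceMatrix:
    """Pairwise sums of branch lengths between tips, in the given species order."""
    mapping = host.find_tips(species)
    pdm = host.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in host.tree.taxon_namespace}
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = taxa[mapping[species[i]]], taxa[mapping[species[j]]]
            d[i, j] = d[j, i] = pdm.patristic_distance(ti, tj)
    return DistanceMatrix(d, ids=list(species))


def tree_clusters(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial clusters (leaf-label sets of internal nodes, excluding the
    root cluster and singletons)."""
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    clusters: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        c = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(c) < len(all_leaves):
            clusters.add(c)
    return clusters
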