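"""Phylogeny input and patristic distance matrices.

Trees are inputs here (Newick strings/files or Nexus trees blocks); the
module validates them, prunes them to the recorded taxa, and converts them
to patristic distance matrices — including the posterior-mean distance
matrix obtained by averaging per-tree matrices over a posterior sample.

Trees are represented as :class:`dendropy.Tree`; distance matrices as
:class:`skbio.DistanceMatrix` with lexicographically sorted taxon labels
so that emitted files are reproducible.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "NewickFormatError",
    "TreeValidationError",
    "TreePosterior",
    "read_newick",
    "read_tree_set",
    "prune_to_taxa",
    "patristic_distances",
    "mean_distance_matrix",
    "write_distance_csv",
    "read_distance_csv",
]


class NewickFormatError(ValueError):
    """Raised when a tree string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates an invariant (duplicate tips,
    missing branch lengths, ...)."""


@dataclass
class TreePosterior:
    """An ordered sample of trees sharing a common tip set."""

    trees: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def common_tips(self) -> frozenset:
        if not self.trees:
            return frozenset()
        return frozenset(_tip_labels(self.trees[0]))


def _tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = _tip_labels(tree)
    if any(lbl is None for lbl in labels):
        raise TreeValidationError("tree has unlabelled tips")
    seen, dupes = set(), set()
    for lbl in labels:
        if lbl in seen:
            dupes.add(lbl)
        seen.add(lbl)
    if dupes:
        raise TreeValidationError(
            f"duplicate tip labels: {sorted(dupes)}"
        )
    # Every non-root edge must carry an explicit length: silently zeroed
    # lengths would corrupt patristic distances.
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon is not None else "<internal>"
            raise TreeValidationError(
                f"missing branch length on edge above {name!r}"
            )
        if edge.length < 0:
            raise TreeValidationError(
                f"negative branch length {edge.length}"
            )
    return tree


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string into a validated tree.

    Quoted labels and scientific-notation branch lengths are accepted.
    Missing branch lengths and duplicate tip labels are rejected.
    """
    if not text or not text.strip():
        raise NewickFormatError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise NewickFormatError(f"Newick parse failure{where}: {exc}") from exc
    return _validate_tree(tree)


def read_tree_set(stream, max_trees: int | None = None) -> TreePosterior:
    """Read a sample of trees (one Newick per line, or a Nexus trees block).

    All trees are validated and pruned to their common tip set; a warning
    is issued when tip sets differ before pruning, and an error raised if
    the intersection has fewer than two taxa.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    if not text.strip():
        raise NewickFormatError("empty tree stream")
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    trees = []
    if schema == "newick":
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            trees.append(read_newick(line))
            if max_trees is not None and len(trees) >= max_trees:
                break
    else:
        try:
            tl = dendropy.TreeList.get(data=text, schema="nexus")
        except Exception as exc:
            raise NewickFormatError(f"Nexus parse failure: {exc}") from exc
        for t in tl:
            trees.append(_validate_tree(t))
            if max_trees is not None and len(trees) >= max_trees:
                break
    if not trees:
        raise NewickFormatError("tree stream contained no trees")

    tip_sets = [frozenset(_tip_labels(t)) for t in trees]
    common = frozenset.intersection(*tip_sets)
    if any(ts != common for ts in tip_sets):
        warnings.warn(
            "trees have heterogeneous tip sets; pruning to the "
            f"{len(common)} shared taxa",
            stacklevel=2,
        )
        if len(common) < 2:
            raise TreeValidationError(
                "fewer than two taxa shared across all trees"
            )
        trees = [prune_to_taxa(t, common) for t in trees]
    return TreePosterior(trees=trees)


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Return a copy of *tree* containing exactly *taxa*.

    Path lengths between retained tips are unchanged (unbranched internal
    nodes are collapsed with branch lengths summed).
    """
    taxa = set(taxa)
    present = set(_tip_labels(tree))
    missing = sorted(taxa - present)
    if missing:
        raise TreeValidationError(f"taxa not in tree: {missing}")
    if len(taxa) < 2:
        raise TreeValidationError("need at least two taxa to prune to")
    pruned = tree.extract_tree_with_taxa_labels(labels=taxa)
    return pruned


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distance matrix of a tree: d(i, j) is the sum of branch
    lengths along the unique path between tips i and j.

    Labels are returned in lexicographic order.
    """
    labels = sorted(_tip_labels(tree))
    if len(labels) < 2:
        raise TreeValidationError("patristic distances need >= 2 tips")
    _validate_tree(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(vals, ids=labels)


def mean_distance_matrix(posterior: TreePosterior) -> DistanceMatrix:
    """Element-wise mean of per-tree patristic matrices over a posterior."""
    if len(posterior) == 0:
        raise ValueError("empty posterior")
    mats = []
    labels = None
    for tree in posterior:
        dm = patristic_distances(tree)
        if labels is None:
            labels = dm.ids
        elif dm.ids != labels:
            raise TreeValidationError(
                "trees in posterior have unequal tip sets"
            )
        mats.append(dm.data)
    return DistanceMatrix(np.mean(mats, axis=0), ids=labels)


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    """Serialize a distance matrix as a labelled CSV (labels in first
    row and column)."""
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path)


def read_distance_csv(path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))
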