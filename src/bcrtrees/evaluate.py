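"""Tree comparison and support metrics: RF cluster distance with short-branch
collapsing, codon-resampling bootstrap, divergence, and percent tree-length
error.

Clades are rooted tip-label sets read off the germline-rooted tree ("subclades"
rather than unrooted bipartitions), matching how B cell lineage trees are
interpreted. Default collapse thresholds are 0.001 mutations per nucleotide
or 0.003 per codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cloneprep import CloneAlignment
from .tree import GERMLINE_LABEL, PhyloTree

__all__ = [
    "RFClusterResult",
    "BootstrapSummary",
    "collapse_short_branches",
    "clade_sets",
    "rf_cluster_distance",
    "codon_bootstrap",
    "divergence",
    "percent_length_error",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {"nucleotide": 0.001, "codon": 0.003}


def _resolve_threshold(threshold, units: str) -> float:
    if threshold is None:
        try:
            threshold = DEFAULT_THRESHOLDS[units]
        except KeyError:
            raise ValueError(f"unknown units {units!r}") from None
    if threshold < 0:
        raise ValueError("collapse threshold must be non-negative")
    return float(threshold)


def collapse_short_branches(
    tree: PhyloTree, threshold: float | None = None, units: str = "nucleotide"
) -> PhyloTree:
    """Contract internal branches shorter than ``threshold`` into polytomies.

    Tip branches are never contracted. Returns a new tree.
    """
    threshold = _resolve_threshold(threshold, units)
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.is_tip or node.parent is None:
                continue
            if (node.length or 0.0) < threshold:
                parent = node.parent
                position = parent.children.index(node)
                parent.children.pop(position)
                for i, child in enumerate(node.children):
                    child.parent = parent
                    parent.children.insert(position + i, child)
                node.children = []
                node.parent = None
                changed = True
    out._reindex()
    return out


def clade_sets(
    tree: PhyloTree, germline_label: str = GERMLINE_LABEL
) -> set[frozenset]:
    """Rooted clades (tip-label sets of internal nodes) after rooting on the
    germline tip; the trivial all-tips cluster and singletons are excluded."""
    rooted = tree.root_on(germline_label)
    out = set()
    for node in rooted.postorder():
        if node.is_tip or node.parent is None:
            continue
        out.add(node.tip_set())
    return out


@dataclass
class RFClusterResult:
    distance: int
    clusters_unique_to_tree1: int
    clusters_unique_to_tree2: int
    collapse_threshold: float


def rf_cluster_distance(
    tree1: PhyloTree,
    tree2: PhyloTree,
    threshold: float | None = None,
    units: str = "nucleotide",
    germline_label: str = GERMLINE_LABEL,
) -> RFClusterResult:
    """RF cluster distance: the number of subclades unique to each tree after
    collapsing branches shorter than ``threshold``. Polytomies are legal, so
    trees need not be strictly binary."""
    threshold = _resolve_threshold(threshold, units)
    if tree1.tip_labels != tree2.tip_labels:
        raise ValueError(
            "tip sets differ: "
            f"only-in-tree1={sorted(tree1.tip_labels - tree2.tip_labels)}, "
            f"only-in-tree2={sorted(tree2.tip_labels - tree1.tip_labels)}"
        )
    c1 = clade_sets(collapse_short_branches(tree1, threshold), germline_label)
    c2 = clade_sets(collapse_short_branches(tree2, threshold), germline_label)
    u1 = len(c1 - c2)
    u2 = len(c2 - c1)
    return RFClusterResult(u1 + u2, u1, u2, threshold)


@dataclass
class BootstrapSummary:
    support: dict  # frozenset(tip labels) -> replicate count
    mean_support: float
    n_replicates: int


def _codon_blocks(aln: CloneAlignment) -> list[tuple[int, list[int]]]:
    """Per partition, the codon start offsets fully inside the partition.

    Partition intervals are padded down to codon boundaries so sampled codons
    never straddle partitions; trailing remainder sites are dropped.
    """
    intervals = [aln.heavy_interval, aln.light_interval]
    blocks = []
    dropped = 0
    for start, stop in intervals:
        width = stop - start
        if width <= 0:
            continue
        n_codons = width // 3
        dropped += width - n_codons * 3
        blocks.append((start, [start + 3 * k for k in range(n_codons)]))
    if dropped:
        warnings.warn(f"{dropped} trailing site(s) not filling a codon were dropped")
    return blocks


def codon_bootstrap(
    aln: CloneAlignment,
    build: Callable[[CloneAlignment], object],
    n: int = 100,
    seed: int = 0,
    threshold: float | None = None,
    units: str = "nucleotide",
) -> BootstrapSummary:
    """Codon-resampling bootstrap support for the full tree's internal branches.

    ``build`` is any tree-building procedure taking a CloneAlignment and
    returning a PhyloTree or a TreeFitResult. Codon columns are sampled with
    replacement within each partition (preserving partition labels); support
    of a branch is the number of replicate trees containing the same tip-set
    cluster after identical short-branch collapsing.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    threshold = _resolve_threshold(threshold, units)

    def get_tree(obj) -> PhyloTree:
        return obj.tree if hasattr(obj, "tree") else obj

    full_tree = get_tree(build(aln))
    full_clades = clade_sets(
        collapse_short_branches(full_tree, threshold), aln.germline_label
    )
    support = {clade: 0 for clade in full_clades}
    blocks = _codon_blocks(aln)
    names = list(aln.sequences_with_germline())

    for _ in range(n):
        pieces: dict[str, list[str]] = {name: [] for name in names}
        intervals = []
        pos = 0
        sequences = aln.sequences_with_germline()
        for _, starts in blocks:
            draw = rng.choice(len(starts), size=len(starts), replace=True)
            for name in names:
                seq = sequences[name]
                pieces[name].extend(seq[starts[k]:starts[k] + 3] for k in draw)
            intervals.append((pos, pos + 3 * len(starts)))
            pos += 3 * len(starts)
        tip_seqs = {n_: "".join(pieces[n_]) for n_ in names if n_ != aln.germline_label}
        rep_aln = CloneAlignment(
            clone_subgroup_id=aln.clone_subgroup_id,
            tip_sequences=tip_seqs,
            germline="".join(pieces[aln.germline_label]),
            heavy_interval=intervals[0],
            light_interval=intervals[1] if len(intervals) > 1 else (pos, pos),
            collapse_map={k: {k} for k in tip_seqs},
            light_present=dict(aln.light_present),
            germline_label=aln.germline_label,
        )
        rep_tree = get_tree(build(rep_aln))
        rep_clades = clade_sets(
            collapse_short_branches(rep_tree, threshold), aln.germline_label
        )
        for clade in support:
            if clade in rep_clades:
                support[clade] += 1

    mean = float(np.mean(list(support.values()))) if support else float("nan")
    return BootstrapSummary(support=support, mean_support=mean, n_replicates=n)


def divergence(
    tree: PhyloTree, tip: str, germline_label: str = GERMLINE_LABEL
) -> float:
    """Sum of branch lengths along the unique germline-to-tip path."""
    if tip == germline_label:
        return 0.0
    rooted = tree.root_on(germline_label)
    node = rooted.find_tip(tip)
    total = 0.0
    while node.parent is not None:
        total += node.length or 0.0
        node = node.parent
    germ = rooted.find_tip(germline_label)
    total += germ.length or 0.0
    return total


def percent_length_error(true_len: float, est_len: float) -> float:
    """(true - estimated) / true; positive means the method underestimated."""
    if true_len <= 0:
        raise ValueError("true tree length must be positive")
    return (true_len - est_len) / true_len
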