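"""Tree inference from clonal alignments: maximum parsimony, single-partition
GTR maximum likelihood, and the scaled multi-partition GTR model.

The main entry point is the statsmodels-style pair
:class:`CloneTreeModel` / :class:`TreeFitResult`::

    model = CloneTreeModel(clone_alignment)
    result = model.fit(method="ml-scaled", seed=1)
    print(result.summary())
    result.tree          # germline-rooted PhyloTree, substitutions/site
    result.light_scalar  # fitted light-chain branch-length scalar

The scaled model shares one topology and branch-length set between heavy and
light partitions, with the light partition's branch lengths multiplied by an
ML-estimated scalar (heavy pinned to 1). Returned branch lengths are always
in alignment-wide expected substitutions per site: for the scaled model the
reference-unit lengths are multiplied by the partition-length-weighted mean
scalar, making tree lengths directly comparable across methods and to
simulation truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cloneprep import CloneAlignment
from .likelihood import MISSING, LikelihoodEngine, encode_sequences
from .models import GTRModel, PartitionScheme
from .parsimony import ParsimonyEngine, fitch_score
from .tree import Node, PhyloTree, star_tree

__all__ = [
    "CloneTreeModel",
    "TreeFitResult",
    "METHODS",
    "ml_search",
    "parsimony_search",
    "partitioned_log_likelihood",
    "optimize_branch_lengths",
    "optimize_scalars_and_model",
    "neighbor_joining_tree",
    "tree_length",
    "fitch_score",
]

METHODS = ("parsimony", "ml-single", "ml-scaled")


def tree_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths; invariant under re-rooting."""
    return float(
        sum(n.length or 0.0 for n in tree.postorder() if n.parent is not None)
    )


def _jc_distance_matrix(aln: CloneAlignment) -> tuple[list[str], np.ndarray]:
    """Pairwise Jukes-Cantor corrected distances with pairwise deletion of
    N/gap positions."""
    taxa, mat = encode_sequences(aln.sequences_with_germline())
    known = (mat < MISSING).astype(np.float64)
    comparable = known @ known.T  # pairwise count of mutually informative sites
    mismatch = np.zeros_like(comparable)
    for state in range(4):
        is_state = (mat == state).astype(np.float64)
        mismatch += is_state @ (known - is_state).T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), 0.0)
    p = np.minimum(p, 0.7499)
    dm = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(dm, 0.0)
    dm = (dm + dm.T) / 2.0
    return taxa, dm


def neighbor_joining_tree(aln: CloneAlignment) -> PhyloTree:
    """Neighbor-joining start tree on JC-corrected distances (germline
    included as a tip). Negative NJ branch lengths are clipped at zero."""
    taxa, dm = _jc_distance_matrix(aln)
    if len(taxa) == 2:
        root = Node()
        root.add_child(Node(taxa[0], dm[0, 1] / 2))
        root.add_child(Node(taxa[1], dm[0, 1] / 2))
        return PhyloTree(root)
    if len(taxa) == 3:
        root = Node()
        d01, d02, d12 = dm[0, 1], dm[0, 2], dm[1, 2]
        lens = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2]
        for name, ln in zip(taxa, lens):
            root.add_child(Node(name, max(ln, 0.0)))
        return PhyloTree(root)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    from .io import read_newick

    sk_tree = nj(DistanceMatrix(dm, ids=taxa))
    newick = str(sk_tree).strip()
    tree = read_newick(newick)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = max(node.length or 0.0, 0.0)
    return tree


@dataclass
class TreeFitResult:
    """Fitted tree plus estimates, diagnostics, and a summary table."""

    tree: PhyloTree
    method: str
    aln: CloneAlignment
    log_likelihood: Optional[float] = None
    parsimony_score: Optional[int] = None
    scheme: Optional[PartitionScheme] = None
    seed: int = 0
    iterations: int = 0
    final_improvement: float = 0.0
    warnings_: list = field(default_factory=list)

    @property
    def tree_length(self) -> float:
        return tree_length(self.tree)

    @property
    def light_scalar(self) -> Optional[float]:
        if self.scheme is None or self.scheme.mode != "scaled":
            return None
        for part in self.scheme.partitions:
            if part.name == "light":
                return part.scalar
        return None

    def summary(self) -> str:
        rows = [
            ("clone", self.aln.clone_subgroup_id),
            ("method", self.method),
            ("n tips", self.aln.n_tips),
            ("alignment length", self.aln.length),
            ("tree length (subs/site)", f"{self.tree_length:.6f}"),
        ]
        if self.log_likelihood is not None:
            rows.append(("log-likelihood", f"{self.log_likelihood:.4f}"))
        if self.parsimony_score is not None:
            rows.append(("parsimony score", self.parsimony_score))
        if self.light_scalar is not None:
            rows.append(("light-chain scalar", f"{self.light_scalar:.4f}"))
        rows.append(("seed", self.seed))
        rows.append(("ascent iterations", self.iterations))
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Clone tree fit", "=" * 30]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)


class CloneTreeModel:
    """Phylogenetic model for one clonal subgroup alignment.

    Parameters
    ----------
    aln:
        Concatenated heavy(+light) alignment with the clonal germline.
    """

    def __init__(self, aln: CloneAlignment):
        self.aln = aln

    @classmethod
    def from_records(cls, subgroup, bundles, collapse: bool = True) -> "CloneTreeModel":
        from .cloneprep import format_clone

        return cls(format_clone(subgroup, bundles, collapse=collapse))

    def fit(self, method: str = "ml-scaled", seed: int = 0, **options) -> TreeFitResult:
        if method == "parsimony":
            return parsimony_search(self.aln, seed=seed, **options)
        if method == "ml-single":
            return ml_search(self.aln, mode="single", seed=seed, **options)
        if method == "ml-scaled":
            return ml_search(self.aln, mode="scaled", seed=seed, **options)
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _default_scheme(aln: CloneAlignment, mode: str) -> PartitionScheme:
    if mode == "single":
        return PartitionScheme.single(aln.length)
    return PartitionScheme.heavy_light(
        aln.heavy_interval, aln.light_interval, mode="scaled"
    )


def partitioned_log_likelihood(
    tree: PhyloTree, aln: CloneAlignment, scheme: PartitionScheme
) -> float:
    """Felsenstein pruning log-likelihood of ``tree`` under ``scheme``."""
    return LikelihoodEngine(aln, scheme, tree).log_likelihood()


def optimize_branch_lengths(
    tree: PhyloTree, aln: CloneAlignment, scheme: PartitionScheme, tol: float = 1e-6
) -> PhyloTree:
    """Optimize every branch by repeated 1-D bounded sweeps; edits in place."""
    LikelihoodEngine(aln, scheme, tree).sweep_branch_lengths(tol=tol)
    return tree


def optimize_scalars_and_model(
    tree: PhyloTree,
    aln: CloneAlignment,
    scheme: PartitionScheme,
    tol: float = 1e-5,
    max_iter: int = 20,
    estimate_rates: bool = True,
) -> PartitionScheme:
    """Coordinate ascent over partition scalars, GTR parameters and branch
    lengths (scaled mode; the heavy scalar stays pinned at 1)."""
    engine = LikelihoodEngine(aln, scheme, tree)
    _coordinate_ascent(engine, tol=tol, max_iter=max_iter, estimate_rates=estimate_rates)
    return scheme


def _coordinate_ascent(
    engine: LikelihoodEngine,
    tol: float = 1e-5,
    max_iter: int = 20,
    estimate_rates: bool = True,
) -> tuple[float, int]:
    lnl = engine.sweep_branch_lengths()
    iterations = 0
    for i in range(max_iter):
        before = lnl
        for p in range(1, len(engine.scheme.partitions)):
            lnl = engine.optimize_scalar(p, window=0.0 if i == 0 else 8.0)
        if estimate_rates and i < 2:
            for p in range(len(engine.scheme.partitions)):
                engine.estimate_model(p, optimize_rates=True)
            lnl = engine.log_likelihood()
        lnl = engine.sweep_branch_lengths(max_sweeps=1)
        iterations = i + 1
        if lnl - before < tol:
            break
    return lnl, iterations


def _trivial_result(aln: CloneAlignment, method: str, seed: int) -> TreeFitResult:
    warnings.warn(
        f"clone {aln.clone_subgroup_id}: fewer than 3 taxa; returning star tree"
    )
    tree = star_tree(sorted(aln.sequences_with_germline()), 0.0)
    return TreeFitResult(tree=tree, method=method, aln=aln, seed=seed)


def ml_search(
    aln: CloneAlignment,
    mode: str = "single",
    seed: int = 0,
    nni: bool = True,
    estimate_rates: bool = True,
    scheme: Optional[PartitionScheme] = None,
) -> TreeFitResult:
    """Maximum likelihood tree search.

    Neighbor-joining start tree, then NNI hill-climbing with branch-length
    re-optimization after each accepted swap (and, in scaled mode, coordinate
    ascent over the light-chain scalar and per-partition GTR parameters).
    The returned tree is rooted on the germline tip.
    """
    taxa = aln.sequences_with_germline()
    if len(taxa) < 3:
        return _trivial_result(aln, f"ml-{mode}", seed)
    if scheme is None:
        scheme = _default_scheme(aln, mode)
    tree = neighbor_joining_tree(aln)
    engine = LikelihoodEngine(aln, scheme, tree)
    for p in range(len(scheme.partitions)):
        engine.estimate_model(p, optimize_rates=False)
    engine.sweep_branch_lengths()
    if estimate_rates:
        for p in range(len(scheme.partitions)):
            engine.estimate_model(p, optimize_rates=True)
    if mode == "scaled":
        # a short pre-search ascent; scalars are polished after the search
        lnl, iterations = _coordinate_ascent(engine, estimate_rates=False, max_iter=3)
    else:
        lnl = engine.sweep_branch_lengths()
        iterations = 1
    if nni and len(taxa) > 3:
        lnl = engine.nni_search()
    if mode == "scaled":
        lnl2, more = _coordinate_ascent(engine, estimate_rates=False)
        final_gain = lnl2 - lnl
        lnl = lnl2
        iterations += more
    else:
        lnl2 = engine.sweep_branch_lengths()
        final_gain = lnl2 - lnl
        lnl = lnl2
    # convert reference-unit branch lengths to alignment-wide subs/site
    factor = scheme.mean_scalar()
    if abs(factor - 1.0) > 1e-12:
        for node in tree.postorder():
            if node.parent is not None and node.length is not None:
                node.length *= factor
    rooted = tree.root_on(aln.germline_label)
    return TreeFitResult(
        tree=rooted,
        method=f"ml-{mode}",
        aln=aln,
        log_likelihood=lnl,
        scheme=scheme,
        seed=seed,
        iterations=iterations,
        final_improvement=final_gain,
    )


def parsimony_search(
    aln: CloneAlignment,
    seed: int = 0,
    ratchet_iters: int = 3,
    assignment: str = "average",
) -> TreeFitResult:
    """Maximum parsimony tree via NNI hill-climb with random-restart ratchet.

    Branch lengths come from parsimony reconstruction (ACCTRAN/DELTRAN
    average by default) in changes per site.
    """
    taxa = aln.sequences_with_germline()
    if len(taxa) < 3:
        return _trivial_result(aln, "parsimony", seed)
    engine = ParsimonyEngine(aln)
    start = neighbor_joining_tree(aln)
    tree, score = engine.search(start, seed=seed, ratchet_iters=ratchet_iters)
    engine.branch_lengths(tree, assignment=assignment)
    rooted = tree.root_on(aln.germline_label)
    return TreeFitResult(
        tree=rooted,
        method="parsimony",
        aln=aln,
        parsimony_score=int(round(score)),
        seed=seed,
    )
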