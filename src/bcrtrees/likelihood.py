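"""Felsenstein pruning under partitioned GTR models.

Sites are compressed to unique column patterns per partition; N and gap
characters carry all-ones conditional vectors (missing at random). Partial
likelihoods are cached per node with dirty-flag invalidation so that
single-branch updates only recompute the path to the root. Per-node scaling
factors guard against underflow on large clones.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize

from .cloneprep import CloneAlignment
from .models import BASE_INDEX, GTRModel, PartitionScheme
from .tree import Node, PhyloTree

__all__ = ["LikelihoodEngine", "encode_sequences", "MIN_BRANCH", "MAX_BRANCH"]

MIN_BRANCH = 1e-9
MAX_BRANCH = 10.0
MISSING = 4  # code for N / gap
_TINY = 1e-300


def _disjoint(a, b) -> bool:
    """Neither node is an ancestor of the other (swap stays a valid tree)."""
    node = a
    while node is not None:
        if node is b:
            return False
        node = node.parent
    node = b
    while node is not None:
        if node is a:
            return False
        node = node.parent
    return True


def encode_sequences(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode sequences as an int8 matrix (A,C,G,T -> 0..3; N/gap -> 4)."""
    taxa = sorted(sequences)
    length = len(next(iter(sequences.values())))
    mat = np.full((len(taxa), length), MISSING, dtype=np.int8)
    for row, name in enumerate(taxa):
        seq = sequences[name]
        if len(seq) != length:
            raise ValueError("sequences have mixed lengths")
        for col, char in enumerate(seq):
            mat[row, col] = BASE_INDEX.get(char, MISSING)
    return taxa, mat


# tip conditional vectors indexed by state code
_TIP_LOOKUP = np.vstack([np.eye(4), np.ones(4)])


class LikelihoodEngine:
    """Partitioned pruning likelihood over one CloneAlignment and tree.

    The tree is manipulated in place (branch lengths, NNI swaps); the engine
    keeps per-node partial caches consistent through ``invalidate`` calls.
    """

    def __init__(self, aln: CloneAlignment, scheme: PartitionScheme, tree: PhyloTree):
        scheme.validate(aln.length)
        self.aln = aln
        self.scheme = scheme
        self.tree = tree
        taxa, mat = encode_sequences(aln.sequences_with_germline())
        if set(taxa) != tree.tip_labels:
            raise ValueError(
                "tree tips do not match alignment: "
                f"only-in-alignment={sorted(set(taxa) - tree.tip_labels)}, "
                f"only-in-tree={sorted(tree.tip_labels - set(taxa))}"
            )
        self._row = {name: i for i, name in enumerate(taxa)}
        # per-partition pattern compression
        self._patterns: list[np.ndarray] = []
        self._counts: list[np.ndarray] = []
        for part in scheme.partitions:
            block = mat[:, part.interval[0]:part.interval[1]]
            if block.shape[1] == 0:
                self._patterns.append(np.zeros((len(taxa), 0), dtype=np.int8))
                self._counts.append(np.zeros(0))
                continue
            pats, counts = np.unique(block, axis=1, return_counts=True)
            self._patterns.append(pats)
            self._counts.append(counts.astype(float))
        self._np = len(scheme.partitions)
        self._partials: list[dict[Node, np.ndarray]] = [dict() for _ in range(self._np)]
        self._logscale: list[dict[Node, np.ndarray]] = [dict() for _ in range(self._np)]
        self._tip_cache: list[dict[str, np.ndarray]] = [dict() for _ in range(self._np)]
        # per-edge messages P(t*c) @ partial(child), keyed by the branch
        # length they were computed at, so optimizing one branch reuses the
        # untouched siblings' work
        self._messages: list[dict[Node, tuple]] = [dict() for _ in range(self._np)]
        self._pmat: list[dict[Node, tuple]] = [dict() for _ in range(self._np)]
        self._plnl: list = [None] * self._np  # cached per-partition lnL
        self.invalidate_all()

    # -- cache management ---------------------------------------------------
    def invalidate_all(self, partition: int | None = None) -> None:
        for p in range(self._np):
            if partition is not None and p != partition:
                continue
            self._partials[p].clear()
            self._logscale[p].clear()
            self._messages[p].clear()
            self._pmat[p].clear()
            self._plnl[p] = None

    def invalidate_upward(self, node: Node) -> None:
        """Drop cached partials on the path from ``node`` to the root."""
        while node is not None:
            for p in range(self._np):
                self._partials[p].pop(node, None)
                self._logscale[p].pop(node, None)
                self._messages[p].pop(node, None)
            node = node.parent
        for p in range(self._np):
            self._plnl[p] = None

    def _tip_partial(self, p: int, label: str) -> np.ndarray:
        cache = self._tip_cache[p]
        if label not in cache:
            codes = self._patterns[p][self._row[label]]
            cache[label] = _TIP_LOOKUP[codes]
        return cache[label]

    def _node_partial(self, p: int, node: Node) -> tuple[np.ndarray, np.ndarray]:
        partials = self._partials[p]
        if node in partials:
            return partials[node], self._logscale[p][node]
        if node.is_tip:
            part = self._tip_partial(p, node.label)
            scale = np.zeros(part.shape[0])
        else:
            model = self.scheme.partitions[p].model
            scalar = self.scheme.partitions[p].scalar
            messages = self._messages[p]
            part = None
            scale = None
            for child in node.children:
                cpart, cscale = self._node_partial(p, child)
                cached = messages.get(child)
                if cached is not None and cached[0] == child.length:
                    msg = cached[1]
                else:
                    pcached = self._pmat[p].get(child)
                    if pcached is not None and pcached[0] == child.length:
                        P = pcached[1]
                    else:
                        P = model.transition_matrix(max(child.length, 0.0) * scalar)
                        self._pmat[p][child] = (child.length, P)
                    msg = cpart @ P.T
                    messages[child] = (child.length, msg)
                part = msg if part is None else part * msg
                scale = cscale if scale is None else scale + cscale
            # rescale to dodge underflow
            m = part.max(axis=1)
            np.maximum(m, _TINY, out=m)
            part = part / m[:, None]
            scale = scale + np.log(m)
        partials[node] = part
        self._logscale[p][node] = scale
        return part, scale

    def partition_log_likelihood(self, p: int) -> float:
        if self._patterns[p].shape[1] == 0:
            return 0.0
        if self._plnl[p] is not None:
            return self._plnl[p]
        part, scale = self._node_partial(p, self.tree.root)
        pi = self.scheme.partitions[p].model.pi
        site = np.log(np.maximum(part @ pi, _TINY)) + scale
        value = float(np.dot(site, self._counts[p]))
        self._plnl[p] = value
        return value

    def log_likelihood(self) -> float:
        lnl = sum(self.partition_log_likelihood(p) for p in range(self._np))
        if not np.isfinite(lnl):
            raise FloatingPointError("non-finite log-likelihood")
        return lnl

    # -- branch lengths -----------------------------------------------------
    def set_branch_length(self, node: Node, t: float) -> None:
        node.length = float(t)
        if node.parent is not None:
            self.invalidate_upward(node.parent)

    def optimize_branch(self, node: Node, xatol: float = 1e-7, window: float = 0.0) -> float:
        """1-D bounded search on the branch above ``node``; returns new lnL.

        With ``window`` > 1 the search first runs on a multiplicative window
        around the current length (cheaper golden-section bracket) and falls
        back to the full [MIN_BRANCH, MAX_BRANCH] range whenever the local
        optimum presses against the window edge. Never decreases the
        likelihood (restores the old length on failure).
        """
        old = node.length
        current = self.log_likelihood()

        def negloglik(t: float) -> float:
            self.set_branch_length(node, t)
            return -self.log_likelihood()

        bounds = (MIN_BRANCH, MAX_BRANCH)
        if window > 1.0 and old is not None and old > 10 * MIN_BRANCH:
            local = (max(old / window, MIN_BRANCH), min(old * window, MAX_BRANCH))
            res = optimize.minimize_scalar(
                negloglik, bounds=local, method="bounded", options={"xatol": xatol}
            )
            at_edge = (
                res.x <= local[0] * 1.05 and local[0] > MIN_BRANCH
            ) or (res.x >= local[1] * 0.95 and local[1] < MAX_BRANCH)
            if not at_edge:
                if -res.fun >= current:
                    self.set_branch_length(node, res.x)
                    return -res.fun
                self.set_branch_length(node, old)
                return current
        res = optimize.minimize_scalar(
            negloglik, bounds=bounds, method="bounded", options={"xatol": xatol}
        )
        if -res.fun >= current:
            self.set_branch_length(node, res.x)
            return -res.fun
        self.set_branch_length(node, old)
        return current

    def sweep_branch_lengths(
        self, tol: float = 1e-6, max_sweeps: int = 20, xatol: float = 1e-7
    ) -> float:
        """Repeated single-branch optimization passes until the total lnL
        gain over a sweep drops below ``tol``. Monotone non-decreasing."""
        lnl = self.log_likelihood()
        for sweep in range(max_sweeps):
            before = lnl
            window = 0.0 if sweep == 0 else 16.0
            for node in list(self.tree.postorder()):
                if node.parent is None:
                    continue
                lnl = self.optimize_branch(node, xatol=xatol, window=window)
            if lnl - before < tol:
                break
        return lnl

    # -- scalars and model parameters ----------------------------------------
    def partition_all_missing(self, p: int) -> bool:
        pats = self._patterns[p]
        if pats.shape[1] == 0:
            return True
        germ = self._row[self.aln.germline_label]
        rows = [i for i in range(pats.shape[0]) if i != germ]
        return bool(np.all(pats[rows] == MISSING))

    def optimize_scalar(
        self, p: int, bounds=(1e-3, 100.0), xatol: float = 1e-6, window: float = 0.0
    ) -> float:
        """ML estimate of partition ``p``'s branch-length scalar."""
        part = self.scheme.partitions[p]
        if self.partition_all_missing(p):
            warnings.warn(
                f"partition {part.name!r} is entirely missing; scalar fixed at 1"
            )
            part.scalar = 1.0
            self.invalidate_all(partition=p)
            return self.log_likelihood()
        old = part.scalar
        current = self.log_likelihood()

        def negloglik(c: float) -> float:
            part.scalar = c
            self.invalidate_all(partition=p)
            return -self.log_likelihood()

        res = None
        if window > 1.0:
            local = (max(old / window, bounds[0]), min(old * window, bounds[1]))
            res = optimize.minimize_scalar(
                negloglik, bounds=local, method="bounded", options={"xatol": xatol}
            )
            if (res.x <= local[0] * 1.05 and local[0] > bounds[0]) or (
                res.x >= local[1] * 0.95 and local[1] < bounds[1]
            ):
                res = None
        if res is None:
            res = optimize.minimize_scalar(
                negloglik, bounds=bounds, method="bounded", options={"xatol": xatol}
            )
        if -res.fun >= current:
            part.scalar = float(res.x)
        else:
            part.scalar = old
        self.invalidate_all(partition=p)
        return self.log_likelihood()

    def empirical_frequencies(self, p: int, pseudocount: float = 1.0) -> np.ndarray:
        pats = self._patterns[p]
        counts = np.zeros(4)
        for state in range(4):
            counts[state] = ((pats == state) * self._counts[p][None, :]).sum()
        counts += pseudocount
        return counts / counts.sum()

    def estimate_model(self, p: int, optimize_rates: bool = True, maxiter: int = 40) -> None:
        """Set partition ``p``'s GTR model: empirical frequencies, and
        exchangeabilities by bounded quasi-Newton ML (GT pinned to 1)."""
        part = self.scheme.partitions[p]
        if self.partition_all_missing(p):
            return
        pi = self.empirical_frequencies(p)
        part.model = GTRModel(pi=pi, rates=part.model.rates)
        self.invalidate_all(partition=p)
        if not optimize_rates:
            return

        def negloglik(log_rates: np.ndarray) -> float:
            rates = np.append(np.exp(log_rates), 1.0)
            part.model = GTRModel(pi=pi, rates=rates)
            self.invalidate_all(partition=p)
            return -self.partition_log_likelihood(p)

        x0 = np.log(part.model.rates[:5] / part.model.rates[5])
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B",
            bounds=[(np.log(0.02), np.log(50.0))] * 5,
            options={"maxiter": maxiter},
        )
        negloglik(res.x)  # leave the fitted model in place

    # -- topology -----------------------------------------------------------
    def swap_subtrees(self, a: Node, b: Node) -> None:
        """Exchange the positions of two disjoint subtrees (NNI move)."""
        pa, pb = a.parent, b.parent
        ia, ib = pa.children.index(a), pb.children.index(b)
        pa.children[ia], pb.children[ib] = b, a
        a.parent, b.parent = pb, pa
        self.invalidate_upward(pa)
        self.invalidate_upward(pb)

    def nni_candidates(self) -> list[tuple[Node, Node]]:
        """Subtree swap pairs across each internal edge (parent u, child v):
        a child of v exchanged with another child of u."""
        out = []
        for v in self.tree.postorder():
            if v.is_tip or v.parent is None:
                continue
            u = v.parent
            siblings = [c for c in u.children if c is not v]
            for a in v.children:
                for c in siblings:
                    out.append((a, c))
        return out

    def nni_search(
        self,
        tol: float = 1e-6,
        max_rounds: int = 10,
        local_xatol: float = 1e-5,
        rescan_scalars: bool = False,
    ) -> float:
        """NNI hill-climb: evaluate each candidate swap with a local branch
        re-optimization, keep it if the likelihood improves by > tol, and run
        a full branch sweep after each accepted swap."""
        lnl = self.sweep_branch_lengths()
        for _ in range(max_rounds):
            improved = False
            for a, c in self.nni_candidates():
                if a.parent is None or c.parent is None or not _disjoint(a, c):
                    continue
                v = a.parent  # internal edge child endpoint
                lengths = (v.length, a.length, c.length)
                self.swap_subtrees(a, c)
                for node in (v, a, c):
                    self.optimize_branch(node, xatol=local_xatol)
                cand = self.log_likelihood()
                if cand > lnl + tol:
                    lnl = self.sweep_branch_lengths()
                    if rescan_scalars:
                        for p in range(1, self._np):
                            lnl = self.optimize_scalar(p)
                    improved = True
                else:
                    self.swap_subtrees(a, c)
                    v.length, a.length, c.length = lengths
                    self.invalidate_upward(v)
                    self.invalidate_upward(a.parent)
            if not improved:
                break
        return lnl
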