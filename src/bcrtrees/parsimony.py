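"""Maximum parsimony: Fitch scoring, ratchet NNI search, and branch lengths
from ACCTRAN/DELTRAN change assignments.

N and gap characters are treated as the full ambiguity set {A,C,G,T}, so an
all-N light partition contributes zero changes anywhere — the mechanism
behind parsimony's branch-length underestimate on missing light chains.
Branch lengths are reported in changes per site; the default assignment
averages accelerated (ACCTRAN) and delayed (DELTRAN) transformation counts
0.5/0.5, which damps the multi-modal artifacts pure ACCTRAN can produce;
pure variants remain available via ``assignment=``.
"""

from __future__ import annotations

import numpy as np

from .cloneprep import CloneAlignment
from .likelihood import MISSING, encode_sequences
from .tree import Node, PhyloTree

__all__ = ["ParsimonyEngine", "fitch_score"]

_INF = np.int32(1 << 20)


class ParsimonyEngine:
    """Fitch/Sankoff machinery over one alignment's compressed site patterns."""

    def __init__(self, aln: CloneAlignment):
        self.aln = aln
        taxa, mat = encode_sequences(aln.sequences_with_germline())
        self._row = {name: i for i, name in enumerate(taxa)}
        pats, counts = np.unique(mat, axis=1, return_counts=True)
        self.patterns = pats
        self.counts = counts.astype(float)
        self.n_sites = int(counts.sum())
        # tip bitmasks: A=1, C=2, G=4, T=8, missing=15
        codes = np.array([1, 2, 4, 8, 15], dtype=np.uint8)
        self._bits = codes[pats]

    def _check_tree(self, tree: PhyloTree) -> None:
        if tree.tip_labels != set(self._row):
            raise ValueError(
                "tree tips do not match alignment: "
                f"missing={sorted(set(self._row) - tree.tip_labels)}, "
                f"extra={sorted(tree.tip_labels - set(self._row))}"
            )

    def score(self, tree: PhyloTree, weights: np.ndarray | None = None) -> float:
        """Fitch score: minimal state changes summed over sites."""
        self._check_tree(tree)
        weights = self.counts if weights is None else weights
        changes = np.zeros(self.patterns.shape[1])
        state: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_tip:
                state[node] = self._bits[self._row[node.label]]
                continue
            acc = None
            for child in node.children:
                s = state.pop(child)
                if acc is None:
                    acc = s
                    continue
                inter = acc & s
                union_mask = inter == 0
                changes += union_mask
                acc = np.where(union_mask, acc | s, inter)
            state[node] = acc
        return float(np.dot(changes, weights))

    # -- Sankoff DP for branch-specific change counts -------------------------
    def _down_costs(self, tree: PhyloTree) -> dict[Node, np.ndarray]:
        costs: dict[Node, np.ndarray] = {}
        npat = self.patterns.shape[1]
        for node in tree.postorder():
            if node.is_tip:
                row = self.patterns[self._row[node.label]]
                c = np.full((npat, 4), _INF, dtype=np.int32)
                known = row < MISSING
                c[known, row[known]] = 0
                c[~known] = 0
                costs[node] = c
            else:
                total = np.zeros((npat, 4), dtype=np.int32)
                for child in node.children:
                    cc = costs[child]
                    best = cc.min(axis=1)
                    total += np.minimum(cc, (best + 1)[:, None])
                costs[node] = total
        return costs

    def branch_changes(
        self, tree: PhyloTree, accelerate: bool
    ) -> dict[Node, np.ndarray]:
        """Per-branch change counts (weighted by pattern counts) under one
        canonical most-parsimonious reconstruction.

        ``accelerate=True`` prefers placing a change on the current branch
        when costs tie (ACCTRAN-like); False delays changes toward the tips
        (DELTRAN-like). Both reconstructions attain the Fitch score.
        """
        self._check_tree(tree)
        costs = self._down_costs(tree)
        npat = self.patterns.shape[1]
        idx = np.arange(npat)
        chosen: dict[Node, np.ndarray] = {}
        changes: dict[Node, np.ndarray] = {}
        for node in tree.preorder():
            c = costs[node]
            if node.parent is None:
                chosen[node] = np.argmin(c, axis=1)
                continue
            parent_state = chosen[node.parent]
            stay = c[idx, parent_state]
            masked = c.copy()
            masked[idx, parent_state] = _INF
            change_state = np.argmin(masked, axis=1)
            change = masked[idx, change_state] + 1
            if accelerate:
                take_change = change <= stay
            else:
                take_change = change < stay
            chosen[node] = np.where(take_change, change_state, parent_state)
            changes[node] = take_change.astype(float)
        return changes

    def branch_lengths(
        self, tree: PhyloTree, assignment: str = "average"
    ) -> None:
        """Set branch lengths in changes/site from parsimony reconstruction."""
        if assignment not in ("average", "acctran", "deltran"):
            raise ValueError(f"unknown assignment {assignment!r}")
        sets = []
        if assignment in ("average", "acctran"):
            sets.append(self.branch_changes(tree, accelerate=True))
        if assignment in ("average", "deltran"):
            sets.append(self.branch_changes(tree, accelerate=False))
        for node in tree.postorder():
            if node.parent is None:
                node.length = None
                continue
            per_branch = [float(np.dot(s[node], self.counts)) for s in sets]
            node.length = (sum(per_branch) / len(per_branch)) / self.n_sites

    # -- topology search -------------------------------------------------------
    def search(
        self,
        start: PhyloTree,
        seed: int = 0,
        ratchet_iters: int = 3,
        max_rounds: int = 50,
    ) -> tuple[PhyloTree, float]:
        """NNI hill-climb with a random-restart ratchet.

        Each ratchet iteration reweights site patterns by bootstrap
        resampling, hill-climbs under the perturbed weights, then re-climbs
        under the original weights, keeping the result only if it improves
        the true score. Ties retain the first-found topology.
        """
        rng = np.random.default_rng(seed)
        tree = start.copy()
        best = self._hill_climb(tree, self.counts, max_rounds)
        for _ in range(ratchet_iters):
            trial = tree.copy()
            weights = rng.multinomial(
                self.n_sites, self.counts / self.n_sites
            ).astype(float)
            self._hill_climb(trial, weights, max_rounds)
            score = self._hill_climb(trial, self.counts, max_rounds)
            if score < best:
                best = score
                tree = trial
        return tree, best

    def _hill_climb(
        self, tree: PhyloTree, weights: np.ndarray, max_rounds: int
    ) -> float:
        current = self.score(tree, weights)
        for _ in range(max_rounds):
            improved = False
            for a, c in _swap_candidates(tree):
                if a.parent is None or c.parent is None or not _disjoint(a, c):
                    continue
                _swap(a, c)
                cand = self.score(tree, weights)
                if cand < current:
                    current = cand
                    improved = True
                else:
                    _swap(a, c)
            if not improved:
                break
        return current


def _swap_candidates(tree: PhyloTree):
    out = []
    for v in tree.postorder():
        if v.is_tip or v.parent is None:
            continue
        u = v.parent
        siblings = [c for c in u.children if c is not v]
        for a in v.children:
            for c in siblings:
                out.append((a, c))
    return out


def _swap(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _disjoint(a: Node, b: Node) -> bool:
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


def fitch_score(tree: PhyloTree, aln: CloneAlignment) -> int:
    """Minimal number of state changes for ``tree`` given ``aln`` (Fitch,
    unordered states; N/gap = full ambiguity)."""
    return int(round(ParsimonyEngine(aln).score(tree)))
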