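"""Independent brute-force oracles used to pin the fast implementations.

These deliberately avoid the package's pruning/Fitch code paths: likelihoods
are computed by enumerating all internal-node state assignments, parsimony
scores by minimizing over the same enumeration, and clade sets by direct
traversal bookkeeping.
"""

from __future__ import annotations

import itertools

import numpy as np

from bcrtrees.models import BASE_INDEX


def brute_force_log_likelihood(tree, aln, scheme) -> float:
    """Sum over all 4^(n internal) ancestral state assignments, per site."""
    seqs = aln.sequences_with_germline()
    total = 0.0
    internals = [n for n in tree.postorder() if not n.is_tip]
    edges = [n for n in tree.postorder() if n.parent is not None]
    for part in scheme.partitions:
        model, c = part.model, part.scalar
        pmats = {n: model.transition_matrix(max(n.length or 0.0, 0.0) * c) for n in edges}
        for site in range(*part.interval):
            like = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))
                prob = model.pi[states[tree.root]]
                for n in edges:
                    P = pmats[n]
                    if n.is_tip:
                        char = seqs[n.label][site]
                        if char in BASE_INDEX:
                            prob *= P[states[n.parent], BASE_INDEX[char]]
                    else:
                        prob *= P[states[n.parent], states[n]]
                like += prob
            total += np.log(like)
    return float(total)


def exhaustive_parsimony_score(tree, aln) -> int:
    """Minimal changes over all internal assignments, summed over sites.
    N/gap tips are free to take any state."""
    seqs = aln.sequences_with_germline()
    internals = [n for n in tree.postorder() if not n.is_tip]
    edges = [n for n in tree.postorder() if n.parent is not None]
    total = 0
    for site in range(aln.length):
        best = None
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = dict(zip(internals, assign))
            changes = 0
            for n in edges:
                parent_state = states[n.parent]
                if n.is_tip:
                    char = seqs[n.label][site]
                    if char not in BASE_INDEX:
                        continue  # ambiguity absorbs any state
                    if BASE_INDEX[char] != parent_state:
                        changes += 1
                elif states[n] != parent_state:
                    changes += 1
            best = changes if best is None else min(best, changes)
        total += best
    return total


def clade_sets_oracle(tree, germline_label="Germline") -> set:
    """Clades by direct enumeration: for every internal node of the
    germline-rooted tree, the set of descendant tips."""
    rooted = tree.root_on(germline_label)
    out = set()

    def tips_below(node):
        if node.is_tip:
            return frozenset([node.label])
        acc = frozenset()
        for child in node.children:
            acc |= tips_below(child)
        return acc

    stack = [rooted.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            if not child.is_tip:
                out.add(tips_below(child))
                stack.append(child)
    return out
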