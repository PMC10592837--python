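"""Ground-truth paired heavy/light simulations.

Two designs are provided:

* 3-taxa "triplet" trees (germline, two tips, three branches) with fixed
  per-branch mutation counts (25 heavy / 12 light by default), optionally
  with one tip's light chain removed — the minimal setting exposing
  missing-light-chain branch-length bias;
* clone-scale simulations: a random rooted topology (uniform coalescent
  joins) with germline at the root, Poisson mutation counts per branch
  (light means halved by default), 5-mer hot/cold-spot targeted
  substitutions, and light-chain dropout masking.

True branch lengths are realized mutation events per concatenated site, so
estimated tree lengths are directly comparable to truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cloneprep import CloneAlignment
from .io import Rearrangement
from .targeting import TargetingModel
from .tree import GERMLINE_LABEL, Node, PhyloTree

__all__ = [
    "MutationEvent",
    "TripletSim",
    "CloneSim",
    "apply_targeted_mutations",
    "generate_naive_pair",
    "simulate_triplet",
    "simulate_clone",
    "mask_light_chains",
    "DEFAULT_HEAVY_LENGTH",
    "DEFAULT_LIGHT_LENGTH",
]

DEFAULT_HEAVY_LENGTH = 360
DEFAULT_LIGHT_LENGTH = 330
_UNMUTABLE = set("N.-")


@dataclass
class MutationEvent:
    position: int
    from_base: str
    to_base: str


def apply_targeted_mutations(
    seq: str,
    n_events: int,
    model: TargetingModel,
    rng: np.random.Generator,
) -> tuple[str, list[MutationEvent]]:
    """Apply ``n_events`` sequential targeted point mutations.

    At each event a position is drawn with probability proportional to its
    current 5-mer mutability (contexts are recomputed after every event, so
    positions can be hit repeatedly and the observed Hamming distance is at
    most ``n_events``); the replacement base follows the context's
    substitution distribution. N and gap positions are never mutated.
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    chars = list(seq)
    length = len(chars)
    if n_events == 0:
        return seq, []
    if length < 5:
        raise ValueError("sequence must be at least 5 nt long")

    def context(i: int) -> str:
        lo, hi = i - 2, i + 3
        pad_left = "N" * max(0, -lo)
        pad_right = "N" * max(0, hi - length)
        return pad_left + "".join(chars[max(lo, 0):min(hi, length)]) + pad_right

    weights = np.array(
        [
            0.0 if chars[i] in _UNMUTABLE else model.mutability(context(i))
            for i in range(length)
        ]
    )
    if weights.sum() <= 0:
        raise ValueError("no mutable positions in sequence")

    events = []
    for _ in range(n_events):
        probs = weights / weights.sum()
        pos = int(rng.choice(length, p=probs))
        old = chars[pos]
        ctx = context(pos)
        new = "ACGT"[int(rng.choice(4, p=model.substitution_probs(ctx, old)))]
        chars[pos] = new
        events.append(MutationEvent(pos, old, new))
        for j in range(max(pos - 2, 0), min(pos + 3, length)):
            weights[j] = (
                0.0 if chars[j] in _UNMUTABLE else model.mutability(context(j))
            )
    return "".join(chars), events


def generate_naive_pair(
    rng: np.random.Generator,
    heavy_length: int = DEFAULT_HEAVY_LENGTH,
    light_length: int = DEFAULT_LIGHT_LENGTH,
) -> tuple[str, str]:
    """Synthetic unmutated heavy/light pair with uniform base composition
    (a stand-in for an empirical naive-cell starting pair)."""
    bases = np.array(list("ACGT"))
    heavy = "".join(rng.choice(bases, size=heavy_length))
    light = "".join(rng.choice(bases, size=light_length))
    return heavy, light


def _synthetic_alignment(
    clone_subgroup_id: str,
    germ_h: str,
    germ_l: str,
    cells: dict[str, tuple[str, Optional[str]]],
) -> CloneAlignment:
    lh, ll = len(germ_h), len(germ_l)
    tips = {}
    light_present = {}
    for name, (heavy, light) in cells.items():
        tips[name] = heavy + (light if light is not None else "N" * ll)
        light_present[name] = light is not None
    return CloneAlignment(
        clone_subgroup_id=clone_subgroup_id,
        tip_sequences=tips,
        germline=germ_h + germ_l,
        heavy_interval=(0, lh),
        light_interval=(lh, lh + ll),
        collapse_map={k: {k} for k in tips},
        light_present=light_present,
    )


@dataclass
class TripletSim:
    """Germline, two tips, three branches with known per-branch event counts.

    Branch 1 runs germline -> internal node, branches 2 and 3 run to tips A
    and B. In the SC+bulk variant tip B's light chain is masked.
    """

    germ_h: str
    germ_l: str
    internal_h: str
    internal_l: str
    tips: dict  # "A"/"B" -> (heavy, light)
    m_heavy: int
    m_light: int
    seed: int

    @property
    def true_branch_length(self) -> float:
        """Per-branch truth in events per concatenated site (all 3 branches)."""
        return (self.m_heavy + self.m_light) / (len(self.germ_h) + len(self.germ_l))

    @property
    def true_tree_length(self) -> float:
        return 3 * self.true_branch_length

    def to_clone_alignment(self, mask_tip_b: bool = False) -> CloneAlignment:
        cells = {
            "A": self.tips["A"],
            "B": (self.tips["B"][0], None) if mask_tip_b else self.tips["B"],
        }
        return _synthetic_alignment("triplet_1", self.germ_h, self.germ_l, cells)

    @property
    def true_tree(self) -> PhyloTree:
        d = self.true_branch_length
        root = Node()
        root.add_child(Node(GERMLINE_LABEL, 0.0))
        inner = root.add_child(Node(None, d))
        inner.add_child(Node("A", d))
        inner.add_child(Node("B", d))
        return PhyloTree(root)

    def to_rearrangements(self, mask_tip_b: bool = False) -> list[Rearrangement]:
        records = []
        for name, (heavy, light) in sorted(self.tips.items()):
            cell = f"triplet_{name}"
            records.append(
                Rearrangement(
                    sequence_id=f"{cell}_H", cell_id=cell, locus="IGH",
                    v_call="IGHV1-1*01", j_call="IGHJ1*01", junction_length=45,
                    sequence_alignment=heavy, germline_alignment=self.germ_h,
                    clone_id="triplet",
                )
            )
            if not (mask_tip_b and name == "B"):
                records.append(
                    Rearrangement(
                        sequence_id=f"{cell}_L", cell_id=cell, locus="IGK",
                        v_call="IGKV1-1*01", j_call="IGKJ1*01", junction_length=33,
                        sequence_alignment=light, germline_alignment=self.germ_l,
                        clone_id="triplet",
                    )
                )
        return records

    def estimated_branch_lengths(self, tree: PhyloTree) -> dict[str, float]:
        """Branch 1/2/3 lengths read off a fitted 3-taxon tree."""
        rooted = tree.root_on(GERMLINE_LABEL)
        out = {}
        for tip, key in ((GERMLINE_LABEL, "branch1"), ("A", "branch2"), ("B", "branch3")):
            out[key] = rooted.find_tip(tip).length or 0.0
        return out


def simulate_triplet(
    m_heavy: int = 25,
    m_light: int = 12,
    seed: int = 0,
    germ: Optional[tuple[str, str]] = None,
    heavy_model: Optional[TargetingModel] = None,
    light_model: Optional[TargetingModel] = None,
    heavy_length: int = DEFAULT_HEAVY_LENGTH,
    light_length: int = DEFAULT_LIGHT_LENGTH,
) -> TripletSim:
    """Simulate one 3-taxa triplet with fixed mutation counts per branch."""
    rng = np.random.default_rng(seed)
    heavy_model = heavy_model or TargetingModel.default()
    light_model = light_model or TargetingModel.default()
    germ_h, germ_l = germ if germ is not None else generate_naive_pair(
        rng, heavy_length, light_length
    )
    internal_h, _ = apply_targeted_mutations(germ_h, m_heavy, heavy_model, rng)
    internal_l, _ = apply_targeted_mutations(germ_l, m_light, light_model, rng)
    tips = {}
    for name in ("A", "B"):
        tip_h, _ = apply_targeted_mutations(internal_h, m_heavy, heavy_model, rng)
        tip_l, _ = apply_targeted_mutations(internal_l, m_light, light_model, rng)
        tips[name] = (tip_h, tip_l)
    return TripletSim(
        germ_h=germ_h,
        germ_l=germ_l,
        internal_h=internal_h,
        internal_l=internal_l,
        tips=tips,
        m_heavy=m_heavy,
        m_light=m_light,
        seed=seed,
    )


@dataclass
class CloneSim:
    """A simulated clone: true tree, tip sequences, and dropout mask."""

    clone_id: str
    true_tree: PhyloTree  # germline-rooted; lengths in events/site
    germ_h: str
    germ_l: str
    cells: dict  # cell_id -> (heavy, light)
    event_counts: dict  # cell-facing bookkeeping: node label -> (heavy, light)
    masked: set = field(default_factory=set)
    rate_ratio: float = 0.5
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def paired_cells(self) -> set:
        return set(self.cells) - self.masked

    def to_rearrangements(self) -> list[Rearrangement]:
        lh, ll = len(self.germ_h), len(self.germ_l)
        records = []
        for i, (cell_id, (heavy, light)) in enumerate(sorted(self.cells.items())):
            records.append(
                Rearrangement(
                    sequence_id=f"{cell_id}_H",
                    cell_id=cell_id,
                    locus="IGH",
                    v_call="IGHV1-1*01",
                    j_call="IGHJ1*01",
                    junction_length=45,
                    sequence_alignment=heavy,
                    germline_alignment=self.germ_h,
                    clone_id=self.clone_id,
                )
            )
            if cell_id not in self.masked:
                records.append(
                    Rearrangement(
                        sequence_id=f"{cell_id}_L",
                        cell_id=cell_id,
                        locus="IGK",
                        v_call="IGKV1-1*01",
                        j_call="IGKJ1*01",
                        junction_length=33,
                        sequence_alignment=light,
                        germline_alignment=self.germ_l,
                        clone_id=self.clone_id,
                    )
                )
        return records

    def to_clone_alignment(self, collapse: bool = True) -> CloneAlignment:
        """Run the observed records through the standard clone-prep pipeline."""
        from .cloneprep import format_clone, resolve_light_chains, split_subgroups
        from .io import group_cells

        bundles, rejected = group_cells(self.to_rearrangements())
        assert not rejected
        assignments = resolve_light_chains(bundles)
        (subgroup, members), = split_subgroups(assignments)
        return format_clone(subgroup, members, collapse=collapse)

    def true_tree_for(self, aln: CloneAlignment, mode: str = "H+L") -> PhyloTree:
        """True tree pruned to the alignment's post-collapse tip set.

        ``mode="H"`` re-expresses branch lengths as heavy-chain events per
        heavy site, the truth against which heavy-only trees are judged.
        """
        tree = self.true_tree.copy()
        if mode == "H":
            lh = len(self.germ_h)
            for node in tree.postorder():
                if node.parent is None or node.label not in self.event_counts:
                    continue
                n_heavy, _ = self.event_counts[node.label]
                node.length = n_heavy / lh
        tree.prune_to(aln.tip_names | {aln.germline_label})
        return tree


def simulate_clone(
    n_tips: int,
    branch_mean_events: float = 4.0,
    rate_ratio: float = 0.5,
    seed: int = 0,
    clone_id: str = "clone1",
    heavy_model: Optional[TargetingModel] = None,
    light_model: Optional[TargetingModel] = None,
    heavy_length: int = DEFAULT_HEAVY_LENGTH,
    light_length: int = DEFAULT_LIGHT_LENGTH,
    germ: Optional[tuple[str, str]] = None,
) -> CloneSim:
    """Simulate one clone down a random rooted topology.

    The topology comes from uniform coalescent-style joins with the germline
    at the root. Per branch, heavy mutation events are Poisson with mean
    ``branch_mean_events`` and light events Poisson with the mean multiplied
    by ``rate_ratio`` (default 0.5: light chains at half the heavy rate).
    True branch lengths are realized events per concatenated site.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    heavy_model = heavy_model or TargetingModel.default()
    light_model = light_model or TargetingModel.default()
    germ_h, germ_l = germ if germ is not None else generate_naive_pair(
        rng, heavy_length, light_length
    )
    total_len = len(germ_h) + len(germ_l)

    lineages = [Node(f"{clone_id}_cell{i + 1:03d}") for i in range(n_tips)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joined = Node()
        joined.add_child(lineages[i])
        joined.add_child(lineages[j])
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(joined)
    root = Node()
    root.add_child(Node(GERMLINE_LABEL, 0.0))
    root.add_child(lineages[0])

    cells: dict[str, tuple[str, str]] = {}
    event_counts: dict[str, tuple[int, int]] = {}
    sequences: dict[Node, tuple[str, str]] = {root: (germ_h, germ_l)}
    counter = 0
    for node in root.preorder():
        if node is root:
            continue
        parent_h, parent_l = sequences[node.parent]
        if node.label == GERMLINE_LABEL:
            node.length = 0.0
            sequences[node] = (parent_h, parent_l)
            continue
        n_heavy = int(rng.poisson(branch_mean_events))
        n_light = int(rng.poisson(branch_mean_events * rate_ratio))
        seq_h, _ = apply_targeted_mutations(parent_h, n_heavy, heavy_model, rng)
        seq_l, _ = apply_targeted_mutations(parent_l, n_light, light_model, rng)
        sequences[node] = (seq_h, seq_l)
        node.length = (n_heavy + n_light) / total_len
        if node.is_tip:
            cells[node.label] = (seq_h, seq_l)
            event_counts[node.label] = (n_heavy, n_light)
        else:
            counter += 1
            node.label = f"{clone_id}_internal{counter}"
            event_counts[node.label] = (n_heavy, n_light)

    return CloneSim(
        clone_id=clone_id,
        true_tree=PhyloTree(root),
        germ_h=germ_h,
        germ_l=germ_l,
        cells=cells,
        event_counts=event_counts,
        rate_ratio=rate_ratio,
        seed=seed,
    )


def mask_light_chains(
    sims: "CloneSim | Sequence[CloneSim]", fraction: float, seed: int = 0
):
    """Randomly discard light chains from a fraction of cells per clone.

    Masks the per-clone share closest to ``fraction`` while always retaining
    at least one cell with a paired light chain.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    single = isinstance(sims, CloneSim)
    sims_list = [sims] if single else list(sims)
    rng = np.random.default_rng(seed)
    out = []
    for sim in sims_list:
        cell_ids = sorted(sim.cells)
        n = len(cell_ids)
        n_mask = min(int(round(fraction * n)), n - 1)
        chosen = set(rng.choice(cell_ids, size=n_mask, replace=False)) if n_mask else set()
        out.append(replace(sim, masked=chosen))
    return out[0] if single else out
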