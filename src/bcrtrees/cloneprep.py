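"""Clone preparation: light-chain subgroup resolution, clonal consensus
germlines, concatenated heavy+light alignments with N-fill for missing light
chains, duplicate collapsing, and matched heavy-only datasets.

Within a clone, cells may carry light chains descending from different VJ
rearrangements (or ambiguous gene calls). Cells are grouped by light-chain
(V gene, J gene, junction length); light-less cells join the subgroup of the
nearest heavy chain by Hamming distance; each subgroup is then treated as a
separate clone for tree building.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import CellBundle, Rearrangement

__all__ = [
    "Subgroup",
    "CloneAlignment",
    "resolve_light_chains",
    "split_subgroups",
    "build_clone_germline",
    "format_clone",
    "make_heavy_only",
    "shm_frequency",
    "hamming_distance",
]

AMBIGUOUS = frozenset("N.-")


def hamming_distance(a: str, b: str) -> int:
    """Mismatches between equal-length strings, skipping positions where
    either has N or a gap character."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(
        1 for x, y in zip(a, b) if x != y and x not in AMBIGUOUS and y not in AMBIGUOUS
    )


@dataclass
class Subgroup:
    """A light-chain VJ subgroup within a clone (1-based index, largest first)."""

    clone_id: str
    subgroup_index: int
    light_v_gene: str
    light_j_gene: str
    light_junction_length: int
    members: set = field(default_factory=set)

    @property
    def clone_subgroup_id(self) -> str:
        return f"{self.clone_id}_{self.subgroup_index}"


def _candidate_keys(bundle: CellBundle) -> set[tuple[str, str, int]]:
    keys = set()
    for light in bundle.lights:
        for v in light.v_genes:
            for j in light.j_genes:
                keys.add((v, j, light.junction_length))
    return keys


def resolve_light_chains(
    bundles: Sequence[CellBundle],
) -> list[tuple[CellBundle, Subgroup]]:
    """Assign every cell of one clone to exactly one light-chain subgroup.

    Cells with light chains are grouped greedily by (light V gene, light J
    gene, junction length), largest candidate grouping first; a cell whose
    ambiguous gene calls span several groups joins the largest compatible
    one (ties: lowest subgroup index). Light-less cells are assigned to the
    subgroup of the heavy chain at minimum Hamming distance (ties: largest
    subgroup, then lowest index). A clone with no light chains at all forms
    one degenerate subgroup.
    """
    if not bundles:
        return []
    clone_ids = {b.heavy.clone_id for b in bundles}
    if len(clone_ids) != 1:
        raise ValueError(f"bundles span multiple clones: {sorted(clone_ids)}")
    clone_id = clone_ids.pop()

    with_light = sorted((b for b in bundles if b.has_light), key=lambda b: b.cell_id)
    without_light = sorted((b for b in bundles if not b.has_light), key=lambda b: b.cell_id)

    candidates = {b.cell_id: _candidate_keys(b) for b in with_light}

    subgroups: list[Subgroup] = []
    assignment: dict[str, Subgroup] = {}
    unassigned = list(with_light)
    while unassigned:
        counts: dict[tuple[str, str, int], int] = {}
        for b in unassigned:
            for key in candidates[b.cell_id]:
                counts[key] = counts.get(key, 0) + 1
        # largest possible grouping; deterministic tie-break on the key itself
        best_key = min(counts, key=lambda k: (-counts[k], k))
        sub = Subgroup(
            clone_id=clone_id,
            subgroup_index=len(subgroups) + 1,
            light_v_gene=best_key[0],
            light_j_gene=best_key[1],
            light_junction_length=best_key[2],
        )
        members = [b for b in unassigned if best_key in candidates[b.cell_id]]
        for b in members:
            sub.members.add(b.cell_id)
            assignment[b.cell_id] = sub
        unassigned = [b for b in unassigned if best_key not in candidates[b.cell_id]]
        subgroups.append(sub)

    if not subgroups:
        # clone with zero light chains anywhere: one degenerate subgroup
        sub = Subgroup(clone_id, 1, "", "", 0)
        for b in without_light:
            sub.members.add(b.cell_id)
        return [(b, sub) for b in without_light]

    # light-less cells: nearest heavy chain among light-bearing members
    lighted_by_cell = {b.cell_id: b for b in with_light}
    for b in without_light:
        best: Optional[tuple[int, int, int]] = None  # (distance, -size, index)
        best_sub = None
        for other in with_light:
            d = hamming_distance(
                b.heavy.sequence_alignment, other.heavy.sequence_alignment
            )
            sub = assignment[other.cell_id]
            rank = (d, -len(sub.members), sub.subgroup_index)
            if best is None or rank < best:
                best = rank
                best_sub = sub
        best_sub.members.add(b.cell_id)
        assignment[b.cell_id] = best_sub

    out = []
    for b in sorted(bundles, key=lambda b: b.cell_id):
        sub = assignment[b.cell_id]
        key = (sub.light_v_gene, sub.light_j_gene, sub.light_junction_length)
        if b.has_light and len(b.lights) > 1:
            # put the light consistent with the subgroup first
            matching = [l for l in b.lights if key in _candidate_keys(
                CellBundle(b.cell_id, b.heavy, (l,)))]
            others = [l for l in b.lights if l not in matching]
            b = CellBundle(b.cell_id, b.heavy, tuple(matching + others))
        out.append((b, sub))
    return out


def split_subgroups(
    assignments: Iterable[tuple[CellBundle, Subgroup]],
) -> list[tuple[Subgroup, list[CellBundle]]]:
    """One (subgroup, members) record set per (clone_id, subgroup_index)."""
    by_sub: dict[tuple[str, int], tuple[Subgroup, list[CellBundle]]] = {}
    for bundle, sub in assignments:
        key = (sub.clone_id, sub.subgroup_index)
        by_sub.setdefault(key, (sub, []))[1].append(bundle)
    return [by_sub[k] for k in sorted(by_sub)]


def build_clone_germline(records: Sequence[Rearrangement]) -> str:
    """Position-wise consensus over member germline alignments.

    Most frequent non-N, non-gap character wins; ties and columns with no
    informative character become N (conservative masking).
    """
    if not records:
        raise ValueError("cannot build a germline from zero records")
    strings = [r.germline_alignment for r in records]
    length = len(strings[0])
    if any(len(s) != length for s in strings):
        raise ValueError("germline alignments have mixed lengths")
    out = []
    for col in zip(*strings):
        counts: dict[str, int] = {}
        for c in col:
            if c not in AMBIGUOUS:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
            continue
        best = max(counts.values())
        winners = [c for c, n in counts.items() if n == best]
        out.append(winners[0] if len(winners) == 1 else "N")
    return "".join(out)


@dataclass
class CloneAlignment:
    """A clonal subgroup's concatenated H+L alignment with partition map."""

    clone_subgroup_id: str
    tip_sequences: dict[str, str]
    germline: str
    heavy_interval: tuple[int, int]
    light_interval: tuple[int, int]
    collapse_map: dict[str, set]
    light_present: dict[str, bool]
    germline_label: str = "Germline"

    def __post_init__(self):
        length = len(self.germline)
        for name, seq in self.tip_sequences.items():
            if len(seq) != length:
                raise ValueError(f"tip {name!r} length != germline length")

    @property
    def length(self) -> int:
        return len(self.germline)

    @property
    def tip_names(self) -> set[str]:
        return set(self.tip_sequences)

    @property
    def n_tips(self) -> int:
        return len(self.tip_sequences)

    def sequences_with_germline(self) -> dict[str, str]:
        return {**self.tip_sequences, self.germline_label: self.germline}

    def to_fasta(self, path, sidecar: Optional[str] = None) -> None:
        from .io import write_fasta

        write_fasta(self.sequences_with_germline(), path)
        if sidecar:
            meta = {
                "clone_subgroup_id": self.clone_subgroup_id,
                "heavy_interval": list(self.heavy_interval),
                "light_interval": list(self.light_interval),
                "collapse_map": {k: sorted(v) for k, v in self.collapse_map.items()},
                "light_present": self.light_present,
            }
            with open(sidecar, "w") as handle:
                json.dump(meta, handle, indent=1)


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x in AMBIGUOUS or y in AMBIGUOUS for x, y in zip(a, b))


def _merge(a: str, b: str) -> str:
    """Fill ambiguous positions of ``a`` with informative characters of ``b``."""
    return "".join(y if x in AMBIGUOUS and y not in AMBIGUOUS else x for x, y in zip(a, b))


def format_clone(
    subgroup: Subgroup,
    bundles: Sequence[CellBundle],
    collapse: bool = True,
) -> CloneAlignment:
    """Concatenate each cell's heavy and light chain into one alignment row.

    Cells lacking a light chain get N-fill over the light interval. With
    ``collapse=True`` (the default), rows that are identical or differ only
    by ambiguous characters are merged into one tip; the collapse map records
    the contributing cells.
    """
    if not bundles:
        raise ValueError("empty subgroup")
    heavies = [b.heavy for b in bundles]
    lh = len(heavies[0].sequence_alignment)
    if any(len(h.sequence_alignment) != lh for h in heavies):
        raise ValueError("mixed heavy alignment lengths")

    lights = [b.light for b in bundles if b.has_light]
    if lights:
        ll = len(lights[0].sequence_alignment)
        if any(len(l.sequence_alignment) != ll for l in lights):
            raise ValueError("mixed light alignment lengths")
    else:
        ll = 0

    heavy_germ = build_clone_germline(heavies)
    light_germ = build_clone_germline(lights) if lights else ""

    rows: list[tuple[str, str, bool]] = []  # (cell_id, concat, has_light)
    for b in sorted(bundles, key=lambda b: b.cell_id):
        light_seq = b.light.sequence_alignment if b.has_light else "N" * ll
        rows.append((b.cell_id, b.heavy.sequence_alignment + light_seq, b.has_light))

    tip_sequences: dict[str, str] = {}
    collapse_map: dict[str, set] = {}
    light_present: dict[str, bool] = {}
    for cell_id, seq, has_light in rows:
        target = None
        if collapse:
            for name, existing in tip_sequences.items():
                if _compatible(existing, seq):
                    target = name
                    break
        if target is None:
            tip_sequences[cell_id] = seq
            collapse_map[cell_id] = {cell_id}
            light_present[cell_id] = has_light
        else:
            tip_sequences[target] = _merge(tip_sequences[target], seq)
            collapse_map[target].add(cell_id)
            light_present[target] = light_present[target] or has_light

    return CloneAlignment(
        clone_subgroup_id=subgroup.clone_subgroup_id,
        tip_sequences=tip_sequences,
        germline=heavy_germ + light_germ,
        heavy_interval=(0, lh),
        light_interval=(lh, lh + ll),
        collapse_map=collapse_map,
        light_present=light_present,
    )


def make_heavy_only(clone: CloneAlignment) -> CloneAlignment:
    """Restrict a formatted clone to its heavy interval.

    The tip set equals the paired clone's post-collapse tip set — matched
    filtering, not re-collapsing — so heavy-only and paired trees are built
    from the same cells and remain comparable.
    """
    start, stop = clone.heavy_interval
    return CloneAlignment(
        clone_subgroup_id=clone.clone_subgroup_id,
        tip_sequences={k: v[start:stop] for k, v in clone.tip_sequences.items()},
        germline=clone.germline[start:stop],
        heavy_interval=(0, stop - start),
        light_interval=(stop - start, stop - start),
        collapse_map={k: set(v) for k, v in clone.collapse_map.items()},
        light_present={k: False for k in clone.tip_sequences},
        germline_label=clone.germline_label,
    )


def shm_frequency(
    seq: str,
    germline: str,
    region: tuple[int, int] = (1, 312),
) -> float:
    """Length-normalized Hamming distance from the germline over an IMGT
    position range (1-based, inclusive; default the V region 1-312).

    Positions with N or a gap in either string are excluded from numerator
    and denominator. Returns NaN when no informative positions remain.
    """
    if len(seq) != len(germline):
        raise ValueError("sequences must have equal length")
    start, stop = region[0] - 1, region[1]  # to 0-based half-open
    stop = min(stop, len(seq))
    mismatches = 0
    informative = 0
    for x, y in zip(seq[start:stop], germline[start:stop]):
        if x in AMBIGUOUS or y in AMBIGUOUS:
            continue
        informative += 1
        if x != y:
            mismatches += 1
    if informative == 0:
        return math.nan
    return mismatches / informative
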