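"""5-mer somatic hypermutation targeting models.

Each 5-mer context maps to a relative mutability of the center base and a
substitution distribution over the four bases (zero on the identity base).
A simplified built-in table elevates the classic WRC/GYW hotspot contexts and
suppresses SYC/GRS coldspots; published 5-mer tables (e.g. S5F-style TSVs)
can be loaded with :meth:`TargetingModel.from_tsv`.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .models import BASE_INDEX, BASES

__all__ = ["TargetingModel", "HOTSPOT_MUTABILITY", "COLDSPOT_MUTABILITY"]

HOTSPOT_MUTABILITY = 4.0
COLDSPOT_MUTABILITY = 0.3

_W = "AT"
_R = "AG"
_S = "CG"
_Y = "CT"


def _classify(fivemer: str) -> float:
    b1, b2, b3, b4, b5 = fivemer
    if b3 == "C" and b1 in _W and b2 in _R:       # WRC hotspot (center C)
        return HOTSPOT_MUTABILITY
    if b3 == "G" and b4 in _Y and b5 in _W:       # GYW hotspot (center G)
        return HOTSPOT_MUTABILITY
    if b3 == "C" and b1 in _S and b2 in _Y:       # SYC coldspot
        return COLDSPOT_MUTABILITY
    if b3 == "G" and b4 in _R and b5 in _S:       # GRS coldspot
        return COLDSPOT_MUTABILITY
    return 1.0


class TargetingModel:
    """Map from 5-mer context to mutability and substitution distribution."""

    def __init__(
        self,
        mutability: dict[str, float],
        substitution: dict[str, np.ndarray] | None = None,
        fallback: float = 1.0,
    ):
        for fivemer, value in mutability.items():
            if value <= 0:
                raise ValueError(f"non-positive mutability for {fivemer}")
        self.mutability_table = mutability
        self.substitution_table = substitution or {}
        self.fallback = fallback

    @classmethod
    def uniform(cls) -> "TargetingModel":
        return cls({})

    @classmethod
    def default(cls) -> "TargetingModel":
        """Built-in simplified hot/cold-spot table over all 1024 5-mers."""
        table = {
            "".join(ctx): _classify("".join(ctx))
            for ctx in itertools.product(BASES, repeat=5)
        }
        return cls(table)

    @classmethod
    def from_tsv(cls, path) -> "TargetingModel":
        """Load a 5-mer table: columns fivemer, mutability, A, C, G, T."""
        df = pd.read_csv(path, sep="\t", dtype={"fivemer": str})
        required = {"fivemer", "mutability"}
        if not required.issubset(df.columns):
            raise ValueError(f"targeting TSV must contain columns {sorted(required)}")
        mutability = {}
        substitution = {}
        has_subs = all(b in df.columns for b in BASES)
        for row in df.itertuples(index=False):
            fivemer = row.fivemer.upper()
            mutability[fivemer] = float(row.mutability)
            if has_subs:
                probs = np.array([getattr(row, b) for b in BASES], float)
                center = BASE_INDEX.get(fivemer[2])
                if center is not None:
                    probs[center] = 0.0
                total = probs.sum()
                if total > 0:
                    substitution[fivemer] = probs / total
        return cls(mutability, substitution)

    def mutability(self, fivemer: str) -> float:
        """Relative mutability; contexts containing N (or off-table) fall
        back to a uniform default."""
        if any(c not in BASE_INDEX for c in fivemer) or len(fivemer) != 5:
            return self.fallback
        return self.mutability_table.get(fivemer, self.fallback)

    def substitution_probs(self, fivemer: str, current: str) -> np.ndarray:
        """Distribution of the replacement base (zero mass on ``current``)."""
        probs = self.substitution_table.get(fivemer)
        if probs is None:
            probs = np.ones(4)
        probs = probs.copy()
        cur = BASE_INDEX.get(current)
        if cur is not None:
            probs[cur] = 0.0
        total = probs.sum()
        if total <= 0:
            probs = np.ones(4)
            probs[cur] = 0.0
            total = 3.0
        return probs / total

    def to_tsv(self, path) -> None:
        rows = []
        for fivemer, mut in sorted(self.mutability_table.items()):
            row = {"fivemer": fivemer, "mutability": mut}
            probs = self.substitution_table.get(fivemer)
            if probs is not None:
                row.update(dict(zip(BASES, probs)))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
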