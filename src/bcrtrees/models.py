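"""General time reversible (GTR) substitution model and partition schemes.

The rate matrix Q is built from base frequencies pi and six symmetric
exchangeabilities (GT fixed to 1 for identifiability) and normalized so the
mean substitution rate under pi is 1; branch lengths are then expected
substitutions per site. Transition probabilities are computed by
eigendecomposition of the pi^(1/2)-symmetrized matrix, with negative
round-off clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GTRModel", "Partition", "PartitionScheme", "BASES", "BASE_INDEX"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# exchangeability order: AC, AG, AT, CG, CT, GT
RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class GTRModel:
    """GTR model with stationary frequencies ``pi`` and exchangeabilities
    ``rates`` in order (AC, AG, AT, CG, CT, GT); GT is the reference rate."""

    def __init__(self, pi=None, rates=None):
        self.pi = np.full(4, 0.25) if pi is None else np.asarray(pi, float)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if np.any(self.pi <= 0):
            raise ValueError("base frequencies must be positive")
        self.rates = np.ones(6) if rates is None else np.asarray(rates, float)
        if np.any(self.rates <= 0):
            raise ValueError("exchangeabilities must be positive")
        self._decompose()

    def _decompose(self) -> None:
        R = np.zeros((4, 4))
        for rate, (i, j) in zip(self.rates, RATE_PAIRS):
            R[i, j] = R[j, i] = rate
        Q = R * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(self.pi, np.diag(Q))
        Q /= mean_rate
        self.Q = Q
        sqrt_pi = np.sqrt(self.pi)
        S = Q * sqrt_pi[:, None] / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((S + S.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]       # diag(pi^-1/2) V
        self._right = (eigvec * sqrt_pi[:, None]).T  # V^T diag(pi^1/2)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    @classmethod
    def from_empirical(cls, counts, rates=None, pseudocount: float = 1.0) -> "GTRModel":
        counts = np.asarray(counts, float) + pseudocount
        return cls(pi=counts / counts.sum(), rates=rates)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GTRModel(pi={np.round(self.pi, 3)}, rates={np.round(self.rates, 3)})"


@dataclass
class Partition:
    """A contiguous alignment block with its own model and branch scalar."""

    name: str
    interval: tuple[int, int]  # half-open
    scalar: float = 1.0
    model: GTRModel = field(default_factory=GTRModel)

    @property
    def width(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class PartitionScheme:
    """Partitions tiling the alignment; ``mode`` is ``single`` or ``scaled``.

    In scaled mode the first (heavy) partition's scalar is the reference and
    stays fixed at 1; only the ratio of scalars is identifiable since a joint
    rescaling is absorbed by the branch lengths.
    """

    partitions: list[Partition]
    mode: str = "single"

    def __post_init__(self):
        if self.mode not in ("single", "scaled"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def validate(self, length: int) -> None:
        pos = 0
        for p in self.partitions:
            if p.interval[0] != pos:
                raise ValueError("partitions do not tile the alignment")
            pos = p.interval[1]
        if pos != length:
            raise ValueError(
                f"partitions cover [0, {pos}) but alignment has length {length}"
            )

    @property
    def total_length(self) -> int:
        return sum(p.width for p in self.partitions)

    def mean_scalar(self) -> float:
        """Partition-length-weighted mean scalar; converts reference-unit
        branch lengths to alignment-wide substitutions per site."""
        widths = [p.width for p in self.partitions if p.width > 0]
        scalars = [p.scalar for p in self.partitions if p.width > 0]
        return float(np.dot(widths, scalars) / np.sum(widths))

    @classmethod
    def single(cls, length: int, model: Optional[GTRModel] = None) -> "PartitionScheme":
        return cls([Partition("all", (0, length), 1.0, model or GTRModel())], "single")

    @classmethod
    def heavy_light(
        cls,
        heavy_interval: tuple[int, int],
        light_interval: tuple[int, int],
        mode: str = "scaled",
        heavy_model: Optional[GTRModel] = None,
        light_model: Optional[GTRModel] = None,
        light_scalar: float = 1.0,
    ) -> "PartitionScheme":
        parts = [Partition("heavy", heavy_interval, 1.0, heavy_model or GTRModel())]
        if light_interval[1] > light_interval[0]:
            parts.append(
                Partition("light", light_interval, light_scalar, light_model or GTRModel())
            )
        return cls(parts, mode)
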