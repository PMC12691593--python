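"""Experiment-design arithmetic for mutation-accumulation (MA) lines.

An MA experiment propagates replicate lines through repeated single-cell
bottlenecks.  Between bottlenecks a colony grows from one cell by doubling
for ``g`` generations, so the effective population size governing selection
during MA is the harmonic mean of the doubling ladder 1, 2, 4, ...; selection
can only overcome drift for mutations with |s| >= 1/Ne in haploids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ExperimentDesign",
    "BottleneckRegime",
    "generations_per_cycle",
    "bottleneck_effective_size",
    "min_selection_coefficient",
    "bottleneck_regime",
]


@dataclass
class ExperimentDesign:
    """Denominator bookkeeping for one species' MA experiment."""

    species: str
    n_lines: int
    n_transfers: int
    generations_total: float  # T, per line
    genome: object | None = None  # GenomeProfile
    per_line_T: dict[str, float] | None = None

    def __post_init__(self):
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.generations_total <= 0:
            raise ValueError("generations_total must be > 0")

    def line_T(self, line_id: str | None = None) -> float:
        if line_id is not None and self.per_line_T and line_id in self.per_line_T:
            return self.per_line_T[line_id]
        return self.generations_total


@dataclass(frozen=True)
class BottleneckRegime:
    generations_per_cycle: float
    ne_ma: float
    s_min: float


def generations_per_cycle(cfu: float) -> float:
    """Generations of doubling needed to grow one cell into a colony of ``cfu`` cells."""
    if cfu < 1:
        raise ValueError("cfu must be >= 1")
    return math.log2(cfu)


def bottleneck_effective_size(g: float) -> float:
    """Harmonic-mean population size over one growth cycle of ``g`` generations.

    Assumes non-overlapping generations, a bottleneck of one cell, and that
    every cell divides, so sizes are 2^t for t = 0..ceil(g)-1.  Approaches
    g/2 for large g.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    n = math.ceil(g)
    return n / sum(2.0 ** -t for t in range(n))


def min_selection_coefficient(ne_ma: float) -> float:
    """Smallest |s| that can overcome drift in a haploid population: 1/Ne."""
    if ne_ma < 1:
        raise ValueError("ne_ma must be >= 1")
    return 1.0 / ne_ma


def bottleneck_regime(g: float) -> BottleneckRegime:
    ne = bottleneck_effective_size(g)
    return BottleneckRegime(g, ne, min_selection_coefficient(ne))
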