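"""Mutation-rate and spectrum estimators.

Per-line rates follow mu = m / (n * T): events per site per generation, with
``n`` the number of sites at which the event class can occur and ``T`` the
line's MA generations.  A species' rate is the mean of its per-line rates;
with uniform T this equals the pooled m_total / (n * T * l) exactly.  The
six-type SNM spectrum conditions each type's denominator on the origin
base-pair class (G:C types divide by G+C sites, A:T types by A+T sites).
Structural-variant rates are per genome per generation: mu = m / T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import ExperimentDesign
from .genome import GenomeProfile
from .variants import SNM_TYPES, LineCallSet

__all__ = [
    "RateEstimate",
    "SpectrumTable",
    "line_rate",
    "pooled_rate",
    "species_rate",
    "spectrum",
    "sv_rate",
    "indel_length_summary",
]

Z95 = 1.96


@dataclass
class RateEstimate:
    """A species-level rate with its dispersion across MA lines.

    ``se`` is the standard error of the mean across lines, s/sqrt(N) with
    ``s`` the standard deviation of per-line rates; a Poisson-based SE
    (sqrt(m_total)/denominator) is available via :meth:`poisson_se`.
    """

    mean_rate: float
    se: float
    m_total: int
    n_sites: float
    per_line: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def ci95_low(self) -> float:
        return self.mean_rate - Z95 * self.se

    @property
    def ci95_high(self) -> float:
        return self.mean_rate + Z95 * self.se

    def poisson_se(self, T: float, n_lines: int) -> float:
        return math.sqrt(self.m_total) / (self.n_sites * T * n_lines)


@dataclass
class SpectrumTable:
    """Conditional rates for the six collapsed SNM types."""

    rows: dict[str, RateEstimate]
    total_snms: int

    def rate(self, snm_type: str) -> float:
        return self.rows[snm_type].mean_rate

    def counts(self) -> dict[str, int]:
        return {t: est.m_total for t, est in self.rows.items()}

    def to_records(self) -> list[dict]:
        out = []
        for t, est in self.rows.items():
            out.append(
                {
                    "type": t,
                    "m": est.m_total,
                    "n_conditional": est.n_sites,
                    "rate": est.mean_rate,
                    "se": est.se,
                    "ci95_low": est.ci95_low,
                    "ci95_high": est.ci95_high,
                }
            )
        return out


def line_rate(m: int, n: float, T: float) -> float:
    """Per-site per-generation rate for one line: m / (n * T)."""
    if n <= 0 or T <= 0:
        raise ValueError("n and T must be positive")
    if m < 0:
        raise ValueError("m must be >= 0")
    return m / (n * T)


def pooled_rate(m_total: int, n: float, T: float, n_lines: int) -> float:
    """Pooled species rate m_total / (n * T * l).

    Equals the mean of per-line rates exactly when every line ran the same
    number of generations.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    return line_rate(m_total, n, T * n_lines)


def _estimate(per_line_m: dict[str, int], n: float, design: ExperimentDesign) -> RateEstimate:
    rates = {lid: line_rate(m, n, design.line_T(lid)) for lid, m in per_line_m.items()}
    values = np.array(list(rates.values()), dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")
    return RateEstimate(
        mean_rate=mean,
        se=se,
        m_total=int(sum(per_line_m.values())),
        n_sites=n,
        per_line=[(lid, per_line_m[lid], rates[lid]) for lid in per_line_m],
    )


def _per_line_counts(design: ExperimentDesign, counts) -> dict[str, int]:
    if isinstance(counts, dict):
        per_line = {str(k): int(v) for k, v in counts.items()}
    else:
        per_line = {f"L{i:03d}": int(v) for i, v in enumerate(counts)}
    if len(per_line) != design.n_lines:
        raise ValueError(
            f"got counts for {len(per_line)} lines but design declares {design.n_lines}"
        )
    return per_line


def species_rate(
    design: ExperimentDesign,
    per_line_counts,
    n_sites: float | None = None,
) -> RateEstimate:
    """Mean of per-line rates with SE across lines.

    ``per_line_counts`` is a mapping line_id -> m or a sequence of counts
    covering every line (zeros included).  ``n_sites`` defaults to the
    design genome's length.
    """
    if n_sites is None:
        if design.genome is None:
            raise ValueError("n_sites not given and design has no genome")
        n_sites = design.genome.length
    return _estimate(_per_line_counts(design, per_line_counts), n_sites, design)


def spectrum(
    callsets: list[LineCallSet],
    profile: GenomeProfile,
    design: ExperimentDesign,
) -> SpectrumTable:
    """Six-type conditional spectrum from classified per-line call sets.

    Lines with no records still contribute zero counts, so ``callsets`` must
    contain one entry per MA line.
    """
    if len(callsets) != design.n_lines:
        raise ValueError(
            f"{len(callsets)} call sets but design declares {design.n_lines} lines"
        )
    per_type: dict[str, dict[str, int]] = {
        t: {cs.line_id: 0 for cs in callsets} for t in SNM_TYPES
    }
    total = 0
    for cs in callsets:
        for rec in cs.snms:
            per_type[rec.snm_type][cs.line_id] += 1
            total += 1
    rows = {}
    for t in SNM_TYPES:
        n_cond = profile.class_sites(t[:2])
        rows[t] = _estimate(per_type[t], n_cond, design)
    return SpectrumTable(rows=rows, total_snms=total)


def sv_rate(design: ExperimentDesign, per_line_sv_counts) -> RateEstimate:
    """Structural-variant rate per genome per generation: mean of m/T across lines."""
    per_line = _per_line_counts(design, per_line_sv_counts)
    return _estimate(per_line, 1.0, design)


def indel_length_summary(callsets: list[LineCallSet]) -> dict[str, dict[str, float]]:
    """Mean absolute length and SE for insertions and deletions."""
    out = {}
    for kind, attr in (("insertion", "insertions"), ("deletion", "deletions")):
        lengths = [abs(r.length_change) for cs in callsets for r in getattr(cs, attr)]
        if lengths:
            arr = np.array(lengths, dtype=float)
            se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
            out[kind] = {"n": len(arr), "mean_length": float(arr.mean()), "se": se}
        else:
            out[kind] = {"n": 0, "mean_length": float("nan"), "se": float("nan")}
    return out
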