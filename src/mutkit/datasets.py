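"""Published summary statistics from mutation-accumulation experiments in
three anaerobically cultured lactic acid bacteria.

These are the experiment's printed inputs — chromosome lengths, line counts,
transfer counts, total generations, event totals, fourfold-synonymous
diversity, and the *Lc. lactis* AT mutation bias and genomic AT composition.
All derived quantities (rates, Ne, equilibrium composition, fixation bias,
drift thresholds) are computed from these by the estimator modules, never
stored.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StudySummary", "LAB_STUDIES"]


@dataclass(frozen=True)
class StudySummary:
    """Per-species inputs of one MA experiment."""

    species: str
    chromosome_length: int  # bp, ancestral chromosome
    gc_percent: float  # genomic GC content, %
    pi_fourfold: float  # pairwise diversity at fourfold-synonymous sites
    n_lines: int  # MA lines entering the rate denominators
    n_transfers: int
    generations_total: float  # T, per line
    snm_total: int
    complex_total: int
    insertion_total: int
    deletion_total: int

    @property
    def indel_total(self) -> int:
        return self.insertion_total + self.deletion_total

    @property
    def generations_per_transfer(self) -> float:
        return self.generations_total / self.n_transfers


LAB_STUDIES: dict[str, StudySummary] = {
    "Lb_acidophilus": StudySummary(
        species="Lb_acidophilus",
        chromosome_length=1_978_850,
        gc_percent=34.7,
        pi_fourfold=1.40e-3,
        n_lines=66,
        n_transfers=50,
        generations_total=1171.0,
        snm_total=3009,
        complex_total=53,
        insertion_total=359,
        deletion_total=683,
    ),
    "Lb_crispatus": StudySummary(
        species="Lb_crispatus",
        chromosome_length=2_239_089,
        gc_percent=37.0,
        pi_fourfold=2.70e-2,
        n_lines=64,
        n_transfers=50,
        generations_total=1084.0,
        snm_total=140,
        complex_total=13,
        insertion_total=18,
        deletion_total=53,
    ),
    "Lc_lactis": StudySummary(
        species="Lc_lactis",
        chromosome_length=2_399_762,
        gc_percent=35.2,
        pi_fourfold=1.69e-2,
        n_lines=50,
        n_transfers=50,
        generations_total=1067.0,
        snm_total=107,
        complex_total=15,
        insertion_total=8,
        deletion_total=11,
    ),
}

# Spectrum-level inputs for Lc. lactis bias algebra: AT mutation bias and the
# precise genomic GC fraction its composition analysis used.
LC_LACTIS_AT_BIAS = 14.53
LC_LACTIS_GC_OBS_PERCENT = 35.24
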