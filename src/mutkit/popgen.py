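"""Nucleotide diversity at fourfold-degenerate sites, Ne estimation, and the
drift-barrier regression.

Under neutrality in haploids, Ne = pi / (2 mu): pairwise diversity restricted
to fourfold-synonymous third-codon positions estimates 2*Ne*mu because those
sites are (nearly) free of coding constraint.  The drift-barrier hypothesis
predicts a negative power-law scaling of the per-site mutation rate with Ne;
the regression here fits log10(rate) on log10(Ne), excluding focal species so
their deviations from the fitted line can be read as observed-vs-predicted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO

__all__ = [
    "FOURFOLD_PREFIXES",
    "DriftBarrierFit",
    "fourfold_sites",
    "nucleotide_diversity",
    "effective_population_size",
    "drift_barrier_regression",
    "read_alignment",
]

# Codon prefixes whose four completions are synonymous in the standard code.
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)

_GAP = "-"


def read_alignment(fasta_path) -> list[str]:
    """Read a multi-FASTA codon alignment as a list of equal-length strings."""
    seqs = [str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in {fasta_path}")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment sequences differ in length")
    return seqs


def fourfold_sites(alignment: list[str]) -> list[int]:
    """0-based indices of third-codon positions that are fourfold degenerate.

    A site qualifies when the first two positions of its codon are gap-free,
    identical across all sequences, and form a fourfold-degenerate prefix in
    the standard genetic code.  Requiring monomorphic context across all
    sequences guarantees every observed third-position state is synonymous.
    """
    if not alignment:
        raise ValueError("empty alignment")
    length = len(alignment[0])
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} not divisible by 3")
    sites = []
    for codon_start in range(0, length, 3):
        prefixes = {seq[codon_start:codon_start + 2] for seq in alignment}
        if len(prefixes) != 1:
            continue
        prefix = next(iter(prefixes))
        if _GAP in prefix or prefix not in FOURFOLD_PREFIXES:
            continue
        sites.append(codon_start + 2)
    return sites


def nucleotide_diversity(alignment: list[str], sites: list[int] | None = None) -> float:
    """Pairwise diversity: mean difference indicator over pairs and sites.

    Gapped states are excluded pairwise, so a site still contributes to the
    pairs at which both sequences carry a base.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    if sites is None:
        sites = fourfold_sites(alignment)
    if not sites:
        raise ValueError("no eligible sites")
    cols = np.array([[seq[i] for i in sites] for seq in alignment])
    diffs = comparisons = 0
    for a, b in itertools.combinations(range(len(alignment)), 2):
        valid = (cols[a] != _GAP) & (cols[b] != _GAP)
        comparisons += int(valid.sum())
        diffs += int(((cols[a] != cols[b]) & valid).sum())
    if comparisons == 0:
        raise ValueError("no gap-free pairwise comparisons at eligible sites")
    return diffs / comparisons


def effective_population_size(pi: float, mu: float) -> float:
    """Haploid Ne = pi / (2 mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (2.0 * mu)


@dataclass
class DriftBarrierFit:
    """OLS of log10(rate) on log10(Ne), fit without the focal species."""

    slope: float
    intercept: float
    r_value: float
    p_value: float
    stderr: float
    predictions: pd.DataFrame  # focal rows: species, ne, rate, predicted_rate, log10_deviation

    def predict(self, ne) -> np.ndarray:
        ne = np.atleast_1d(np.asarray(ne, dtype=float))
        return 10.0 ** (self.intercept + self.slope * np.log10(ne))


def drift_barrier_regression(table: pd.DataFrame, focal_species=()) -> DriftBarrierFit:
    """Fit the mutation-rate/Ne scaling law and score focal species against it.

    ``table`` needs columns ``species``, ``ne``, ``rate`` (all ne, rate > 0).
    Rows whose species is in ``focal_species`` are excluded from the fit and
    returned with predicted rates and signed log10 deviations
    (observed - predicted).
    """
    focal = set(focal_species)
    if not {"species", "ne", "rate"} <= set(table.columns):
        raise ValueError("table must have columns species, ne, rate")
    if (table["ne"] <= 0).any() or (table["rate"] <= 0).any():
        raise ValueError("ne and rate must be positive")
    background = table[~table["species"].isin(focal)]
    if len(background) < 3:
        raise ValueError("need at least 3 non-focal rows")
    x = np.log10(background["ne"].to_numpy(dtype=float))
    y = np.log10(background["rate"].to_numpy(dtype=float))
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all Ne equal")
    fit = stats.linregress(x, y)
    focal_rows = table[table["species"].isin(focal)].copy()
    predicted = 10.0 ** (fit.intercept + fit.slope * np.log10(focal_rows["ne"].to_numpy(dtype=float))) \
        if len(focal_rows) else np.array([])
    focal_rows["predicted_rate"] = predicted
    focal_rows["log10_deviation"] = (
        np.log10(focal_rows["rate"].to_numpy(dtype=float)) - np.log10(predicted)
        if len(focal_rows) else np.array([])
    )
    return DriftBarrierFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        predictions=focal_rows.reset_index(drop=True),
    )
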