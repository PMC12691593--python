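"""Neutrality checks and origin-distance positional-bias analysis.

If mutations accumulate neutrally and independently, per-line counts should
follow a Poisson (or, allowing line-to-line rate heterogeneity, a negative
binomial) distribution, and mutations should fall in coding sequence in
proportion to its share of the chromosome.  A positional bias is screened by
binning the chromosome, computing per-bin conditional rates
mu = m / (n * T * l), and rank-correlating rate against circular distance
from the replication origin (Spearman, Bonferroni-corrected across types).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ExperimentDesign
from .genome import GenomeBin, GenomeProfile
from .variants import SNM_TYPES, MutationRecord

__all__ = [
    "DispersionTestResult",
    "BinnedRateSeries",
    "CorrelationResult",
    "dispersion_test",
    "coding_enrichment_test",
    "binned_rates",
    "origin_distance_correlation",
]


@dataclass
class DispersionTestResult:
    distribution: str  # "negative_binomial" | "poisson"
    mean: float
    dispersion: float | None  # NB size parameter (inverse overdispersion)
    chi2: float
    df: int
    p: float
    table: pd.DataFrame  # category, observed, expected


@dataclass
class BinnedRateSeries:
    """Per-bin per-type conditional rates, mu = m / (n * T * l)."""

    table: pd.DataFrame  # bin, start, end, origin_distance, type, m, n, rate
    n_lines: int
    T: float

    def for_type(self, snm_type: str) -> pd.DataFrame:
        return self.table[self.table["type"] == snm_type].reset_index(drop=True)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_raw: float
    p_bonferroni: float
    n_bins: int


def _nb_loglik(size: float, counts: np.ndarray, mean: float) -> float:
    p = size / (size + mean)
    return float(stats.nbinom.logpmf(counts, size, p).sum())


def _pool_expected(support: np.ndarray, expected: np.ndarray, observed: np.ndarray):
    """Pool categories from both tails until every expected count is >= 5."""
    cats = [[str(s), float(o), float(e)] for s, o, e in zip(support, observed, expected)]
    while len(cats) > 1 and cats[-1][2] < 5:
        last = cats.pop()
        cats[-1][0] = f">={cats[-1][0].lstrip('>=')}"
        cats[-1][1] += last[1]
        cats[-1][2] += last[2]
    while len(cats) > 1 and cats[0][2] < 5:
        first = cats.pop(0)
        cats[0][0] = f"<={cats[0][0].lstrip('<=')}"
        cats[0][1] += first[1]
        cats[0][2] += first[2]
    # interior categories can still dip below 5: merge each into its neighbor
    while len(cats) > 1:
        exps = [c[2] for c in cats]
        i = int(np.argmin(exps))
        if exps[i] >= 5:
            break
        j = i + 1 if i + 1 < len(cats) and (i == 0 or cats[i + 1][2] <= cats[i - 1][2]) else i - 1
        lo, hi = sorted((i, j))
        cats[lo] = [f"{cats[lo][0]}-{cats[hi][0]}",
                    cats[lo][1] + cats[hi][1], cats[lo][2] + cats[hi][2]]
        cats.pop(hi)
    labels = [c[0] for c in cats]
    obs = np.array([c[1] for c in cats])
    exp = np.array([c[2] for c in cats])
    return labels, obs, exp


def dispersion_test(per_line_counts) -> DispersionTestResult:
    """Goodness-of-fit of per-line mutation counts to a count distribution.

    Fits a negative binomial by maximum likelihood (mean fixed at the sample
    mean, size parameter optimized from a method-of-moments start) and tests
    the fit with a chi-square statistic on categories pooled from the tails
    until each expected count reaches 5 (Cochran's rule).  Falls back to a
    Poisson fit when the sample variance does not exceed the mean, including
    the degenerate all-identical case.
    """
    counts = np.asarray(list(per_line_counts), dtype=int)
    if counts.size < 2:
        raise ValueError("need at least two lines")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))

    upper = int(counts.max()) + 1
    support = np.arange(upper + 1)

    if var <= mean or mean == 0:
        if var == 0:
            warnings.warn("all per-line counts identical; Poisson fit is degenerate")
        distribution, size = "poisson", None
        pmf = stats.poisson.pmf(support, mean)
        n_params = 1
    else:
        size0 = mean**2 / (var - mean)  # method-of-moments start
        res = optimize.minimize_scalar(
            lambda log_size: -_nb_loglik(np.exp(log_size), counts, mean),
            bounds=(np.log(size0) - 8, np.log(size0) + 8),
            method="bounded",
        )
        size = float(np.exp(res.x))
        distribution = "negative_binomial"
        pmf = stats.nbinom.pmf(support, size, size / (size + mean))
        n_params = 2

    expected = pmf * counts.size
    expected[-1] = counts.size - expected[:-1].sum()  # fold the upper tail in
    observed = np.array([(counts == k).sum() for k in support], dtype=float)
    observed[-1] = (counts >= support[-1]).sum()

    labels, obs, exp = _pool_expected(support, expected, observed)
    df = len(obs) - 1 - n_params
    if df < 1:
        warnings.warn("too few categories after pooling; p-value unavailable")
        chi2, p = float("nan"), float("nan")
        df = max(df, 0)
    else:
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2, df))
    return DispersionTestResult(
        distribution=distribution,
        mean=mean,
        dispersion=size,
        chi2=chi2,
        df=df,
        p=p,
        table=pd.DataFrame({"category": labels, "observed": obs, "expected": exp}),
    )


def coding_enrichment_test(records, profile: GenomeProfile) -> tuple[float, float]:
    """Chi-square test of SNM placement in coding vs noncoding sequence.

    Expectation is proportional to interval lengths; 1 degree of freedom.
    """
    if not profile.coding_intervals:
        raise ValueError("profile has no coding intervals")
    coding_len = profile.coding_length
    frac = coding_len / profile.length
    if frac in (0.0, 1.0):
        raise ValueError("coding fraction must be strictly between 0 and 1")
    snms = [r for r in records if r.mclass == "SNM"]
    m = len(snms)
    if m == 0:
        raise ValueError("no SNMs to test")
    starts = np.array([s for s, _ in profile.coding_intervals])
    ends = np.array([e for _, e in profile.coding_intervals])
    pos = np.array([r.position for r in snms])
    idx = np.searchsorted(starts, pos, side="right") - 1
    in_coding = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
    observed = np.array([in_coding.sum(), m - in_coding.sum()], dtype=float)
    expected = np.array([m * frac, m * (1 - frac)])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def binned_rates(
    records,
    bins: list[GenomeBin],
    design: ExperimentDesign,
    snm_types=SNM_TYPES,
) -> BinnedRateSeries:
    """Per-bin per-type conditional rates over the binned chromosome."""
    length = bins[-1].end
    starts = np.array([b.start for b in bins])
    T, l = design.generations_total, design.n_lines
    counts = {(b.index, t): 0 for b in bins for t in snm_types}
    for rec in records:
        if rec.mclass != "SNM" or rec.snm_type not in snm_types:
            continue
        if not 1 <= rec.position <= length:
            raise ValueError(f"record position {rec.position} outside [1, {length}]")
        b = int(np.searchsorted(starts, rec.position, side="right") - 1)
        counts[(b, rec.snm_type)] += 1
    rows = []
    for b in bins:
        for t in snm_types:
            n = b.gc_sites if t.startswith("GC") else b.at_sites
            m = counts[(b.index, t)]
            rows.append(
                {
                    "bin": b.index,
                    "start": b.start,
                    "end": b.end,
                    "origin_distance": b.origin_distance,
                    "type": t,
                    "m": m,
                    "n": n,
                    "rate": m / (n * T * l) if n > 0 else float("nan"),
                }
            )
    return BinnedRateSeries(table=pd.DataFrame(rows), n_lines=l, T=T)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) <= 9:
        # exact permutation null over pairings
        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic

        res = stats.permutation_test(
            (y,), statistic, permutation_type="pairings",
            n_resamples=np.inf, alternative="two-sided",
        )
        return float(res.statistic), float(res.pvalue)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def origin_distance_correlation(
    series: BinnedRateSeries,
    n_tests: int = 6,
    snm_types=SNM_TYPES,
) -> dict[str, CorrelationResult]:
    """Spearman correlation of per-bin rate vs distance to the origin.

    Average ranks on ties; exact permutation p for <= 9 bins, t-approximation
    otherwise; Bonferroni correction multiplies by ``n_tests`` (default 6,
    one test per SNM type).
    """
    out = {}
    for t in snm_types:
        sub = series.for_type(t).dropna(subset=["rate"])
        if len(sub) < 5:
            raise ValueError(f"need >= 5 bins with defined rates for {t}")
        x = sub["origin_distance"].to_numpy(dtype=float)
        y = sub["rate"].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            out[t] = CorrelationResult(float("nan"), float("nan"), float("nan"), len(sub))
            continue
        rho, p = _spearman(x, y)
        out[t] = CorrelationResult(rho, p, min(1.0, p * n_tests), len(sub))
    return out
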