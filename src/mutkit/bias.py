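"""Mutation-bias summaries: Ts/Tv, AT mutation bias, equilibrium composition,
and fixation bias.

The AT mutation bias beta is the ratio of the conditional rate of mutations
converting G:C sites to A:T over the reverse.  Under mutation pressure alone
a genome drifts to an equilibrium AT fraction alpha_eq = beta/(1+beta); when
the observed composition alpha_obs departs from that equilibrium, the gap is
attributed to a fixation bias phi (relative fixation rate of new AT vs GC
alleles), obtained from alpha_obs ~ beta*phi/(1+beta*phi), i.e.
phi = alpha_obs / (beta * (1 - alpha_obs)).  A phi below one means new GC
alleles fix preferentially; the GC-directed bias 1/phi is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rates import SpectrumTable
from .variants import SNM_TYPES, TRANSITION_TYPES

__all__ = [
    "BiasSummary",
    "at_mutation_bias",
    "equilibrium_composition",
    "fixation_bias",
    "ts_tv",
    "summarize_bias",
]

_GC_ORIGIN = tuple(t for t in SNM_TYPES if t.startswith("GC"))
_AT_ORIGIN = tuple(t for t in SNM_TYPES if t.startswith("AT"))


@dataclass(frozen=True)
class BiasSummary:
    ts_tv: float
    beta: float | None
    alpha_eq: float | None
    gc_eq: float | None
    phi: float | None
    gc_fixation_bias: float | None


def at_mutation_bias(spectrum: SpectrumTable, numerator: str = "transition") -> float:
    """AT mutation bias beta from conditional (per-site) rates.

    ``numerator="transition"`` (default) takes the GC>AT transition class over
    the AT>GC class; ``numerator="all"`` takes all GC-origin classes over all
    AT-origin classes.  Rates rather than raw counts are used so genome
    composition cancels.
    """
    if numerator == "transition":
        num = spectrum.rate("GC>AT")
        den = spectrum.rate("AT>GC")
    elif numerator == "all":
        num = sum(spectrum.rate(t) for t in _GC_ORIGIN)
        den = sum(spectrum.rate(t) for t in _AT_ORIGIN)
    else:
        raise ValueError("numerator must be 'transition' or 'all'")
    if den == 0:
        raise ZeroDivisionError("AT-origin rate is zero; beta undefined")
    return num / den


def equilibrium_composition(beta: float) -> tuple[float, float]:
    """(alpha_eq, gc_eq): the AT and GC fractions at mutational equilibrium."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    alpha_eq = beta / (1.0 + beta)
    return alpha_eq, 1.0 - alpha_eq


def fixation_bias(beta: float, alpha_obs: float) -> tuple[float, float]:
    """(phi, 1/phi): AT-fixation bias implied by the observed AT fraction."""
    if not 0.0 < alpha_obs < 1.0:
        raise ValueError("alpha_obs must be strictly inside (0, 1)")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    phi = alpha_obs / (beta * (1.0 - alpha_obs))
    return phi, 1.0 / phi


def ts_tv(counts: dict[str, int], rates: dict[str, float] | None = None) -> float:
    """Transition/transversion ratio; count-based by default.

    Pass the per-type rate map via ``rates`` for the rate-based variant.
    Returns ``inf`` when no transversions were observed.
    """
    source = rates if rates is not None else counts
    ts = sum(v for t, v in source.items() if t in TRANSITION_TYPES)
    tv = sum(v for t, v in source.items() if t not in TRANSITION_TYPES)
    if tv == 0:
        return float("inf")
    return ts / tv


def summarize_bias(
    spectrum: SpectrumTable,
    alpha_obs: float | None = None,
    numerator: str = "transition",
) -> BiasSummary:
    """Bundle the bias statistics for one species.

    A spectrum without AT>GC events leaves beta undefined (None); without
    GC>AT events beta is 0 and the fixation bias is undefined.
    """
    try:
        beta = at_mutation_bias(spectrum, numerator=numerator)
    except ZeroDivisionError:
        beta = None
    if beta is None:
        alpha_eq = gc_eq = None
    else:
        alpha_eq, gc_eq = equilibrium_composition(beta)
    phi = gc_bias = None
    if alpha_obs is not None and beta:
        phi, gc_bias = fixation_bias(beta, alpha_obs)
    return BiasSummary(
        ts_tv=ts_tv(spectrum.counts()),
        beta=beta,
        alpha_eq=alpha_eq,
        gc_eq=gc_eq,
        phi=phi,
        gc_fixation_bias=gc_bias,
    )
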