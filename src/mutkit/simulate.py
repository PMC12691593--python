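"""Synthetic mutation-accumulation experiments with known truth.

The generator mirrors the model the estimators assume: per line and SNM type,
the event count is Poisson (optionally negative-binomial with matched mean)
with expectation rate * class_sites * T, positions fall on eligible sites of
the type's origin class, and a site mutates at most once per line (per-site
rates of order 1e-8 over ~1e3 generations make double hits negligible).  An
optional origin-proximal gradient multiplies one type's placement weight by
f(d) = 1 + (k - 1) * max(0, 1 - d/w), a linear decay from k-fold at the
origin to flat beyond window w — the minimal one-parameter shape for an
origin-centred rate enrichment.  Indels are placed uniformly with geometric
lengths.  All randomness flows through one :class:`numpy.random.Generator`,
so a config plus seed reproduces byte-identical outputs.

Default parameters correspond to the largest experiment the analysis stack
is sized for: 66 lines, 1,171 generations, a 2 Mb chromosome at 34.7% GC,
a strongly GC>AT-dominated spectrum with high Ts/Tv, and indel rates of a
few 1e-9 per site per generation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome import profile_genome, GenomeProfile
from .popgen import FOURFOLD_PREFIXES
from .variants import SNM_TYPES

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "simulate_ma_experiment",
    "simulate_codon_alignment",
    "write_experiment",
]

# alt base implied by a collapsed type for each possible ref base
_ALT_FOR = {
    ("G", "GC>AT"): "A", ("C", "GC>AT"): "T",
    ("G", "GC>TA"): "T", ("C", "GC>TA"): "A",
    ("G", "GC>CG"): "C", ("C", "GC>CG"): "G",
    ("A", "AT>GC"): "G", ("T", "AT>GC"): "C",
    ("A", "AT>TA"): "T", ("T", "AT>TA"): "A",
    ("A", "AT>CG"): "C", ("T", "AT>CG"): "G",
}

_DEFAULT_RATES = {
    "GC>AT": 1.2e-8,
    "AT>GC": 8.0e-9,
    "GC>TA": 2.0e-10,
    "GC>CG": 1.0e-10,
    "AT>TA": 2.0e-10,
    "AT>CG": 1.0e-10,
}


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic MA experiment."""

    genome_length: int = 2_000_000
    gc_fraction: float = 0.347
    origin: int = 1
    coding_fraction: float = 0.85
    n_lines: int = 66
    T: float = 1171.0
    rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RATES))
    dispersion: str = "poisson"  # or "negative_binomial"
    nb_size: float = 10.0  # NB size parameter when dispersion is negative_binomial
    gradient_type: str | None = None  # one SNM type, or None for flat
    gradient_k: float = 1.0  # fold-enrichment at the origin
    gradient_w: int = 250_000  # decay window, bp
    ins_rate: float = 2.4e-9  # per site per generation
    del_rate: float = 4.5e-9
    ins_mean_length: float = 1.0
    del_mean_length: float = 1.5
    seed: int | None = None

    def __post_init__(self):
        if set(self.rates) - set(SNM_TYPES):
            raise ValueError(f"unknown SNM types: {set(self.rates) - set(SNM_TYPES)}")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be >= 0")
        if self.gradient_k < 1:
            raise ValueError("gradient_k must be >= 1")
        if self.gradient_w > self.genome_length // 2:
            raise ValueError("gradient_w must be <= genome_length/2")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.dispersion not in ("poisson", "negative_binomial"):
            raise ValueError("dispersion must be 'poisson' or 'negative_binomial'")


@dataclass
class SimulationTruth:
    """The config plus realized counts and positions, for recovery tests."""

    config: SimulationConfig
    sequence: str
    coding_intervals: list[tuple[int, int]]
    per_line_counts: dict[str, dict[str, int]]  # line -> type/class -> count

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "coding_intervals": self.coding_intervals,
            "per_line_counts": self.per_line_counts,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genome(config: SimulationConfig, rng=None) -> GenomeProfile:
    """Draw an iid ancestral chromosome and lay down coding blocks.

    Bases are iid with P(G) = P(C) = gc_fraction/2; coding sequence is placed
    as 1 kb blocks spaced evenly to total ``coding_fraction`` of the genome.
    """
    rng = _rng(config.seed if rng is None else rng)
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_length, p=p)
    sequence = bases.tobytes().decode("ascii")

    intervals: list[tuple[int, int]] = []
    if config.coding_fraction > 0:
        block = min(1000, config.genome_length)
        period = max(block, int(round(block / config.coding_fraction)))
        start = 1
        while start <= config.genome_length:
            end = min(start + block - 1, config.genome_length)
            intervals.append((start, end))
            start += period
        # trim to hit the requested fraction as closely as whole blocks allow
        target = int(round(config.coding_fraction * config.genome_length))
        total = sum(e - s + 1 for s, e in intervals)
        while intervals and total - (intervals[-1][1] - intervals[-1][0] + 1) >= target:
            s, e = intervals.pop()
            total -= e - s + 1
    return profile_genome(sequence, origin=config.origin, coding_intervals=intervals)


def _gradient_weights(idx0: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Placement weight f(d) for 0-based site indices."""
    pos = idx0 + 1
    d = np.abs(pos - config.origin)
    d = np.minimum(d, config.genome_length - d)
    return 1.0 + (config.gradient_k - 1.0) * np.maximum(0.0, 1.0 - d / config.gradient_w)


def _draw_count(rng, lam: float, config: SimulationConfig) -> int:
    if lam == 0:
        return 0
    if config.dispersion == "poisson":
        return int(rng.poisson(lam))
    size = config.nb_size
    return int(rng.negative_binomial(size, size / (size + lam)))


def _sample_sites(rng, candidates: np.ndarray, weights, count: int, used: np.ndarray) -> np.ndarray:
    """Sample ``count`` distinct unused sites, weighted; rejection-based."""
    if count == 0:
        return np.empty(0, dtype=np.int64)
    if count > candidates.size:
        raise ValueError("expected count exceeds eligible sites")
    chosen: list[int] = []
    p = None
    if weights is not None:
        p = weights / weights.sum()
    for _ in range(100):
        need = count - len(chosen)
        if need == 0:
            break
        draw = rng.choice(candidates, size=2 * need + 10, replace=True, p=p)
        for site in draw:
            if not used[site]:
                used[site] = True
                chosen.append(int(site))
                if len(chosen) == count:
                    break
    if len(chosen) < count:
        raise RuntimeError("site sampling failed to converge; rates too dense")
    return np.array(sorted(chosen), dtype=np.int64)


def simulate_ma_experiment(
    config: SimulationConfig,
    rng=None,
    profile: GenomeProfile | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate per-line mutation calls and the generating truth.

    Returns a DataFrame in the mutation-table schema (line_id, position, ref,
    alt) covering every line, and a :class:`SimulationTruth`.  Pass a
    pre-built ``profile`` to reuse one ancestral genome across replicates.
    """
    rng = _rng(config.seed if rng is None else rng)
    if profile is None:
        profile = simulate_genome(config, rng)
    seq = profile.sequence
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    class_sites = {
        "AT": np.flatnonzero((arr == ord("A")) | (arr == ord("T"))),
        "GC": np.flatnonzero((arr == ord("G")) | (arr == ord("C"))),
    }
    for t, rate in config.rates.items():
        lam = rate * class_sites[t[:2]].size * config.T
        if lam > class_sites[t[:2]].size:
            raise ValueError(f"rate for {t} implies more events than eligible sites")

    weights = {}
    if config.gradient_type is not None and config.gradient_k > 1:
        cls = config.gradient_type[:2]
        weights[config.gradient_type] = _gradient_weights(class_sites[cls], config)

    rows = []
    per_line_counts: dict[str, dict[str, int]] = {}
    line_ids = [f"L{i:03d}" for i in range(config.n_lines)]
    for line_id in line_ids:
        used = np.zeros(config.genome_length, dtype=bool)
        counts: dict[str, int] = {}
        for t in SNM_TYPES:
            rate = config.rates.get(t, 0.0)
            sites = class_sites[t[:2]]
            count = _draw_count(rng, rate * sites.size * config.T, config)
            positions = _sample_sites(rng, sites, weights.get(t), count, used)
            counts[t] = int(positions.size)
            for p0 in positions:
                ref = seq[p0]
                rows.append((line_id, int(p0) + 1, ref, _ALT_FOR[(ref, t)]))
        # indels: uniform placement, geometric lengths
        for kind, rate, mean_len in (
            ("insertion", config.ins_rate, config.ins_mean_length),
            ("deletion", config.del_rate, config.del_mean_length),
        ):
            count = _draw_count(rng, rate * config.genome_length * config.T, config)
            counts[kind] = count
            geom_p = 1.0 / max(mean_len, 1.0)
            for _ in range(count):
                p0 = int(rng.integers(0, config.genome_length - 60))
                while used[p0]:
                    p0 = int(rng.integers(0, config.genome_length - 60))
                used[p0] = True
                length = min(int(rng.geometric(geom_p)), 49)
                anchor = seq[p0]
                insert = (
                    rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
                    .tobytes().decode("ascii")
                )
                if kind == "insertion":
                    rows.append((line_id, p0 + 1, anchor, anchor + insert))
                else:
                    rows.append((line_id, p0 + 1, seq[p0:p0 + length + 1], anchor))
        per_line_counts[line_id] = counts

    table = pd.DataFrame(rows, columns=["line_id", "position", "ref", "alt"])
    table = table.sort_values(["line_id", "position"], kind="stable").reset_index(drop=True)
    truth = SimulationTruth(
        config=config,
        sequence=seq,
        coding_intervals=list(profile.coding_intervals),
        per_line_counts=per_line_counts,
    )
    return table, truth


def simulate_codon_alignment(
    n_sequences: int,
    n_codons: int,
    target_pi: float,
    seed=None,
) -> list[str]:
    """Codon alignment whose fourfold third positions have expected pairwise
    diversity ``target_pi``.

    For targets up to 0.5 each third position carries two alleles at
    frequency p with 2p(1-p) = target_pi; above 0.5 (max 0.75) four alleles
    at frequencies (q, q, q, 1-3q) are used.
    """
    if not 0.0 <= target_pi <= 0.75:
        raise ValueError("target_pi must be in [0, 0.75]")
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = _rng(seed)
    prefixes = rng.choice(sorted(FOURFOLD_PREFIXES), size=n_codons)
    bases = np.array(list("ACGT"))
    if target_pi <= 0.5:
        p = (1.0 - np.sqrt(1.0 - 2.0 * target_pi)) / 2.0
        freqs = np.array([p, 1.0 - p, 0.0, 0.0])
    else:
        q = (6.0 - np.sqrt(36.0 - 48.0 * target_pi)) / 24.0
        freqs = np.array([q, q, q, 1.0 - 3.0 * q])
    thirds = rng.choice(bases, size=(n_sequences, n_codons), p=freqs)
    return [
        "".join(pref + thirds[i, j] for j, pref in enumerate(prefixes))
        for i in range(n_sequences)
    ]


def write_experiment(config: SimulationConfig, out_dir, seed=None) -> dict:
    """Simulate and write ancestor FASTA, mutation TSV, design TSV, truth JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed if seed is None else seed)
    profile = simulate_genome(config, rng)
    table, truth = simulate_ma_experiment(config, rng, profile=profile)

    fasta = out / "ancestor.fasta"
    with open(fasta, "w") as fh:
        fh.write(">ancestor synthetic\n")
        for i in range(0, len(truth.sequence), 80):
            fh.write(truth.sequence[i:i + 80] + "\n")
    table.to_csv(out / "mutations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{
            "species": "synthetic",
            "n_lines": config.n_lines,
            "n_transfers": 50,
            "generations_total": config.T,
        }]
    ).to_csv(out / "design.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(truth.to_json())
    return {
        "fasta": str(fasta),
        "mutations": str(out / "mutations.tsv"),
        "design": str(out / "design.tsv"),
        "truth": str(out / "truth.json"),
    }
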