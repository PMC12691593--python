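"""Ancestral-chromosome model: composition, circular coordinates, and binning.

The chromosome is the denominator of every rate in a mutation-accumulation
(MA) analysis: per-site rates divide by the number of sites at which a
mutation class can occur, and positional analyses divide the chromosome into
bins with per-bin class counts.  Coordinates are 1-based throughout, matching
VCF/GFF conventions.  The chromosome is treated as circular for distance
computations (bacterial replichores run both ways from *oriC*) but linear for
binning: bins tile ``[1, length]`` and never wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeProfile",
    "GenomeBin",
    "profile_genome",
    "circular_distance",
    "bin_genome",
    "load_genome",
    "read_intervals",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeBin:
    """One tile of the chromosome with per-class site tallies.

    ``start`` and ``end`` are 1-based and inclusive; consecutive bins satisfy
    ``next.start == end + 1``.  ``origin_distance`` is the circular distance
    from the bin start to the replication origin.
    """

    index: int
    start: int
    end: int
    at_sites: int
    gc_sites: int
    origin_distance: int

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeProfile:
    """Base composition and coordinate frame of an ancestral chromosome.

    Ambiguous bases (N) count toward ``length`` but are excluded from the
    class-specific site tallies: a site that cannot be assigned to the A:T or
    G:C class cannot host a classified mutation.
    """

    name: str
    length: int
    counts: dict[str, int]
    gc_fraction: float
    origin: int = 1
    coding_intervals: list[tuple[int, int]] = field(default_factory=list)
    circular: bool = True
    sequence: str | None = None

    @property
    def at_sites(self) -> int:
        return self.counts["A"] + self.counts["T"]

    @property
    def gc_sites(self) -> int:
        return self.counts["G"] + self.counts["C"]

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_intervals)

    def class_sites(self, origin_class: str) -> int:
        """Number of sites in an origin class, ``"AT"`` or ``"GC"``."""
        if origin_class == "AT":
            return self.at_sites
        if origin_class == "GC":
            return self.gc_sites
        raise ValueError(f"unknown origin class {origin_class!r}")

    def is_coding(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.coding_intervals)


def _merge_intervals(intervals) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(tuple(map(int, iv)) for iv in intervals):
        if s > e:
            raise ValueError(f"malformed interval ({s}, {e}): start > end")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def profile_genome(
    sequence: str,
    origin: int = 1,
    coding_intervals=(),
    name: str = "chromosome",
    circular: bool = True,
) -> GenomeProfile:
    """Build a :class:`GenomeProfile` from a nucleotide sequence.

    Parameters
    ----------
    sequence
        Chromosome sequence over A/C/G/T/N, case-insensitive.
    origin
        1-based coordinate of the replication origin (*oriC*).
    coding_intervals
        Iterable of 1-based closed intervals; overlaps are merged.
    """
    seq = str(sequence).upper()
    if not seq:
        raise ValueError("empty sequence")
    alphabet = set(seq)
    if not alphabet <= _VALID_BASES:
        raise ValueError(f"invalid characters in sequence: {sorted(alphabet - _VALID_BASES)}")
    length = len(seq)
    if not 1 <= origin <= length:
        raise ValueError(f"origin {origin} outside [1, {length}]")
    counts = {b: seq.count(b) for b in "ACGT"}
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        raise ValueError("sequence contains no unambiguous bases")
    merged = _merge_intervals(coding_intervals)
    if merged and (merged[0][0] < 1 or merged[-1][1] > length):
        raise ValueError("coding intervals outside [1, length]")
    return GenomeProfile(
        name=name,
        length=length,
        counts=counts,
        gc_fraction=(counts["G"] + counts["C"]) / unambiguous,
        origin=origin,
        coding_intervals=merged,
        circular=circular,
        sequence=seq,
    )


def circular_distance(pos: int, origin: int, length: int) -> int:
    """Shortest distance between two coordinates on a circular chromosome."""
    if not (1 <= pos <= length and 1 <= origin <= length):
        raise ValueError("coordinates out of range")
    d = abs(pos - origin)
    return min(d, length - d)


def bin_genome(
    profile: GenomeProfile,
    fixed_width: int | None = None,
    fixed_count: int | None = None,
) -> list[GenomeBin]:
    """Tile the chromosome into bins with per-class site counts.

    Exactly one of ``fixed_width`` (bp per bin, last bin may be short) or
    ``fixed_count`` (number of bins; width = length // count, last bin absorbs
    the remainder) must be given.  Requires the profile to carry its sequence.
    """
    if (fixed_width is None) == (fixed_count is None):
        raise ValueError("specify exactly one of fixed_width, fixed_count")
    if profile.sequence is None:
        raise ValueError("profile lacks sequence; per-bin class counts need it")
    length = profile.length
    edges: list[tuple[int, int]] = []
    if fixed_width is not None:
        if not 1 <= fixed_width <= length:
            raise ValueError("fixed_width must be in [1, length]")
        start = 1
        while start <= length:
            edges.append((start, min(start + fixed_width - 1, length)))
            start += fixed_width
    else:
        if not 1 <= fixed_count <= length:
            raise ValueError("fixed_count must be in [1, length]")
        width = length // fixed_count
        for i in range(fixed_count):
            start = i * width + 1
            end = (i + 1) * width if i < fixed_count - 1 else length
            edges.append((start, end))

    arr = np.frombuffer(profile.sequence.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    cum_at = np.concatenate([[0], np.cumsum(is_at)])
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])

    bins = []
    for i, (s, e) in enumerate(edges):
        bins.append(
            GenomeBin(
                index=i,
                start=s,
                end=e,
                at_sites=int(cum_at[e] - cum_at[s - 1]),
                gc_sites=int(cum_gc[e] - cum_gc[s - 1]),
                origin_distance=circular_distance(s, profile.origin, length),
            )
        )
    return bins


def load_genome(
    fasta_path,
    origin: int = 1,
    intervals_path=None,
    circular: bool = True,
) -> GenomeProfile:
    """Read the first FASTA record as the chromosome (plasmids ignored)."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA records in {fasta_path}")
    intervals = read_intervals(intervals_path) if intervals_path else ()
    return profile_genome(
        str(record.seq), origin=origin, coding_intervals=intervals,
        name=record.id, circular=circular,
    )


def read_intervals(path) -> list[tuple[int, int]]:
    """Read a BED-like 3-column file (0-based half-open) into 1-based closed intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"interval line has <3 columns: {line!r}")
            start0, end0 = int(fields[1]), int(fields[2])
            out.append((start0 + 1, end0))
    return _merge_intervals(out)
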