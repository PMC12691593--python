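"""Reading, filtering, and classifying per-line mutation calls.

Input is either the package's tab-separated mutation-table schema
(``line_id, position, ref, alt`` plus optional QC columns) or a minimal
haploid VCF.  Single-nucleotide mutations (SNMs) are collapsed by strand
symmetry into six types (e.g. ``GC>AT`` covers both G→A and C→T), the
convention under which conditional rates are computed downstream.

Filters are opt-in and conservative: records lacking a QC field required by a
threshold are retained, because the main inputs are post-filter call tables
or synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SNM_TYPES",
    "TRANSITION_TYPES",
    "TRANSVERSION_TYPES",
    "DEFAULT_HARD_FILTERS",
    "MutationRecord",
    "LineCallSet",
    "classify_substitution",
    "classify",
    "read_mutation_table",
    "read_vcf",
    "apply_hard_filters",
    "subtract_ancestral",
    "cluster_complex",
    "write_mutation_table",
]

SNM_TYPES = ("GC>AT", "GC>TA", "GC>CG", "AT>GC", "AT>TA", "AT>CG")
TRANSITION_TYPES = frozenset({"GC>AT", "AT>GC"})
TRANSVERSION_TYPES = frozenset(SNM_TYPES) - TRANSITION_TYPES

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Pyrimidine-context lookup: (ref, alt) -> collapsed type, built from the
# strand-collapse rule type(X>Y) == type(comp(X)>comp(Y)).
_SNM_LOOKUP = {
    ("G", "A"): "GC>AT", ("C", "T"): "GC>AT",
    ("G", "T"): "GC>TA", ("C", "A"): "GC>TA",
    ("G", "C"): "GC>CG", ("C", "G"): "GC>CG",
    ("A", "G"): "AT>GC", ("T", "C"): "AT>GC",
    ("A", "T"): "AT>TA", ("T", "A"): "AT>TA",
    ("A", "C"): "AT>CG", ("T", "G"): "AT>CG",
}

# Inclusive thresholds as conventionally applied to haploid GATK calls:
# a record is kept when field op value holds.
DEFAULT_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "F_MISSING": ("eq", 0.0),
    "QD": ("ge", 2.0),
    "SOR": ("le", 5.0),
    "FS": ("le", 60.0),
    "MQ": ("ge", 40.0),
    "MQRankSum": ("ge", -20.0),
    "ReadPosRankSum": ("ge", -8.0),
    "QUAL": ("ge", 30.0),
}

_QC_COLUMNS = tuple(DEFAULT_HARD_FILTERS)


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation in one MA line."""

    line_id: str
    position: int
    ref: str
    alt: str
    mclass: str  # SNM | insertion | deletion | complex | invalid
    snm_type: str | None = None
    length_change: int = 0
    qc: dict | None = None
    members: tuple = ()  # populated for complex events


@dataclass
class LineCallSet:
    """Retained and excluded records for one MA line.

    ``excluded`` holds ``(record, reason)`` pairs; together with ``records``
    it accounts for every input row.
    """

    line_id: str
    records: list[MutationRecord] = field(default_factory=list)
    excluded: list[tuple[MutationRecord, str]] = field(default_factory=list)

    @property
    def snms(self) -> list[MutationRecord]:
        return [r for r in self.records if r.mclass == "SNM"]

    @property
    def insertions(self) -> list[MutationRecord]:
        return [r for r in self.records if r.mclass == "insertion"]

    @property
    def deletions(self) -> list[MutationRecord]:
        return [r for r in self.records if r.mclass == "deletion"]

    @property
    def complexes(self) -> list[MutationRecord]:
        return [r for r in self.records if r.mclass == "complex"]


def classify_substitution(ref: str, alt: str) -> str:
    """Collapsed six-type class of a single-base substitution."""
    key = (ref.upper(), alt.upper())
    if key not in _SNM_LOOKUP:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return _SNM_LOOKUP[key]


def classify(line_id: str, position: int, ref: str, alt: str, qc=None) -> MutationRecord:
    """Classify one (ref, alt) pair into an SNM, insertion, or deletion record."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"ref equals alt at {position}")
    if len(ref) == 1 and len(alt) == 1:
        return MutationRecord(line_id, position, ref, alt, "SNM",
                              snm_type=classify_substitution(ref, alt), qc=qc)
    mclass = "insertion" if len(alt) > len(ref) else "deletion"
    return MutationRecord(line_id, position, ref, alt, mclass,
                          length_change=len(alt) - len(ref), qc=qc)


def read_mutation_table(path) -> list[LineCallSet]:
    """Read the TSV mutation-table schema into per-line call sets.

    Required columns: ``line_id``, ``position``, ``ref``, ``alt``.  Any of the
    QC columns (QD, SOR, FS, MQ, MQRankSum, ReadPosRankSum, QUAL, F_MISSING)
    are attached to records when present.  Rows with ``ref == alt`` or a
    non-numeric position are rejected into ``excluded`` with a logged reason.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["line_id", "position", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    qc_cols = [c for c in _QC_COLUMNS if c in df.columns]

    callsets: dict[str, LineCallSet] = {}
    for row in df.itertuples(index=False):
        line_id = str(row.line_id)
        cs = callsets.setdefault(line_id, LineCallSet(line_id))
        qc = None
        if qc_cols:
            qc = {}
            for c in qc_cols:
                v = getattr(row, c)
                if v is not None and not pd.isna(v):
                    qc[c] = float(v)
        try:
            position = int(row.position)
        except (TypeError, ValueError):
            bad = MutationRecord(line_id, -1, str(row.ref), str(row.alt), "invalid", qc=qc)
            cs.excluded.append((bad, f"non-numeric position {row.position!r}"))
            logger.warning("rejected row in %s: non-numeric position %r", line_id, row.position)
            continue
        try:
            cs.records.append(classify(line_id, position, str(row.ref), str(row.alt), qc=qc))
        except ValueError as err:
            bad = MutationRecord(line_id, position, str(row.ref), str(row.alt), "invalid", qc=qc)
            cs.excluded.append((bad, str(err)))
            logger.warning("rejected row in %s: %s", line_id, err)
    for cs in callsets.values():
        cs.records.sort(key=lambda r: r.position)
    return [callsets[k] for k in sorted(callsets)]


def read_vcf(path, chromosome: str | None = None) -> list[LineCallSet]:
    """Import a minimal haploid VCF: one call set per sample column.

    Multi-allelic rows are split into one record per alternate allele.  INFO
    keys matching the hard-filter fields plus QUAL are attached as QC fields;
    F_MISSING is computed from the genotype column when absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    callsets = {s: LineCallSet(s) for s in samples}
    for variant in vcf:
        if chromosome is not None and variant.CHROM != chromosome:
            continue
        genotypes = variant.genotypes  # [allele..., phased]
        n_missing = sum(1 for g in genotypes if g[0] < 0)
        qc = {"F_MISSING": n_missing / max(len(samples), 1)}
        if variant.QUAL is not None:
            qc["QUAL"] = float(variant.QUAL)
        for key in ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
            val = variant.INFO.get(key)
            if val is not None:
                qc[key] = float(val)
        for alt_index, alt in enumerate(variant.ALT, start=1):
            for sample, g in zip(samples, genotypes):
                if g[0] == alt_index:
                    callsets[sample].records.append(
                        classify(sample, variant.POS, variant.REF, alt, qc=dict(qc))
                    )
    for cs in callsets.values():
        cs.records.sort(key=lambda r: r.position)
    return [callsets[s] for s in samples]


def _passes(record: MutationRecord, key: str, op: str, value: float) -> bool:
    if record.qc is None or key not in record.qc:
        return True  # filters are opt-in: absent fields never exclude
    x = record.qc[key]
    if op == "ge":
        return x >= value
    if op == "le":
        return x <= value
    if op == "eq":
        return x == value
    raise ValueError(f"unknown comparison {op!r}")


def apply_hard_filters(calls: LineCallSet, thresholds=None) -> LineCallSet:
    """Move records failing any hard-filter threshold to ``excluded``.

    ``thresholds`` maps field name to ``(op, value)`` with op in
    {"ge", "le", "eq"}; defaults to :data:`DEFAULT_HARD_FILTERS` (inclusive
    bounds, so a record exactly at a threshold is retained).
    """
    if thresholds is None:
        thresholds = DEFAULT_HARD_FILTERS
    unknown = set(thresholds) - set(DEFAULT_HARD_FILTERS)
    if unknown:
        raise KeyError(f"unknown hard-filter fields: {sorted(unknown)}")
    out = LineCallSet(calls.line_id, excluded=list(calls.excluded))
    for rec in calls.records:
        failed = [k for k, (op, v) in thresholds.items() if not _passes(rec, k, op, v)]
        if failed:
            out.excluded.append((rec, f"hard filter: {','.join(failed)}"))
        else:
            out.records.append(rec)
    return out


def subtract_ancestral(calls: LineCallSet, ancestral_variants) -> LineCallSet:
    """Exclude exact (position, ref, alt) matches to known ancestral differences."""
    keys = {(int(p), r.upper(), a.upper()) for p, r, a in ancestral_variants}
    out = LineCallSet(calls.line_id, excluded=list(calls.excluded))
    for rec in calls.records:
        if (rec.position, rec.ref, rec.alt) in keys:
            out.excluded.append((rec, "ancestral difference"))
        else:
            out.records.append(rec)
    return out


def cluster_complex(calls: LineCallSet, window: int = 50) -> LineCallSet:
    """Collapse proximal mutations within a line into single complex events.

    Maximal chains of records whose consecutive position gaps are strictly
    less than ``window`` are replaced by one record of class ``complex``
    (multi-nucleotide mutation); chain members move to ``excluded``.  Chains
    may mix SNMs and indels.  Records exactly ``window`` apart stay separate.
    """
    recs = sorted(calls.records, key=lambda r: r.position)
    out = LineCallSet(calls.line_id, excluded=list(calls.excluded))
    chain: list[MutationRecord] = []

    def flush(chain):
        if len(chain) == 1:
            out.records.append(chain[0])
            return
        out.records.append(
            MutationRecord(
                calls.line_id, chain[0].position,
                ref="", alt="", mclass="complex",
                length_change=sum(r.length_change for r in chain),
                members=tuple(chain),
            )
        )
        for r in chain:
            out.excluded.append((r, "complex cluster member"))

    for rec in recs:
        if chain and rec.position - chain[-1].position < window:
            chain.append(rec)
        else:
            if chain:
                flush(chain)
            chain = [rec]
    if chain:
        flush(chain)
    out.records.sort(key=lambda r: r.position)
    return out


def write_mutation_table(callsets, path) -> None:
    """Write call sets back to the TSV schema (complex members re-expanded)."""
    rows = []
    for cs in callsets:
        for rec in cs.records:
            targets = rec.members if rec.mclass == "complex" else (rec,)
            for r in targets:
                row = {"line_id": r.line_id, "position": r.position, "ref": r.ref, "alt": r.alt}
                if r.qc:
                    row.update(r.qc)
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
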