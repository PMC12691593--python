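import numpy as np
import pytest

from mutkit.design import ExperimentDesign
from mutkit.genome import profile_genome
from mutkit.variants import LineCallSet, classify


@pytest.fixture
def toy_profile():
    """100 bp genome: 'ATGC' * 25 — 50 A:T and 50 G:C sites."""
    return profile_genome("ATGC" * 25, origin=10)


@pytest.fixture
def toy_design(toy_profile):
    return ExperimentDesign("toy", n_lines=2, n_transfers=5,
                            generations_total=10.0, genome=toy_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_callset(line_id, calls):
    """Build a LineCallSet from (position, ref, alt) triples."""
    cs = LineCallSet(line_id)
    for pos, ref, alt in calls:
        cs.records.append(classify(line_id, pos, ref, alt))
    cs.records.sort(key=lambda r: r.position)
    return cs


def callsets_from_table(table, n_lines):
    """Classify a simulated mutation table into one call set per line."""
    by_line = {f"L{i:03d}": LineCallSet(f"L{i:03d}") for i in range(n_lines)}
    for row in table.itertuples(index=False):
        by_line[row.line_id].records.append(
            classify(row.line_id, int(row.position), row.ref, row.alt)
        )
    return list(by_line.values())
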