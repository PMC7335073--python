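"""Shared fixtures: small substrate layouts and in-memory simulated runs."""

from __future__ import annotations

import io as _io

import pytest

from methylflank import (
    PreferenceModel,
    SubstrateLayout,
    emit_hairpin_fastq,
    generate_pool,
    simulate_methylation,
)
from methylflank.hairpin import HairpinRead


@pytest.fixture
def layout() -> SubstrateLayout:
    return SubstrateLayout()


@pytest.fixture
def small_layout() -> SubstrateLayout:
    """Short flanks keep simulated pools fast while exercising every stage."""
    return SubstrateLayout(flank_len=3)


def simulate_reads(
    layout: SubstrateLayout,
    n: int,
    model: PreferenceModel,
    seed: int,
    conversion_rate: float = 1.0,
    inappropriate_conversion: float = 0.0,
    seq_error: float = 0.0,
    **fastq_kwargs,
):
    """Pool -> outcomes -> parsed HairpinReads, all in memory."""
    pool = generate_pool(n, layout.flank_len, layout.central_motif, seed,
                         layout=layout)
    outcomes = simulate_methylation(pool, model, seed + 1)
    buf = _io.StringIO()
    emit_hairpin_fastq(pool, outcomes, conversion_rate, inappropriate_conversion,
                       seq_error, seed + 2, buf, layout=layout, **fastq_kwargs)
    reads = []
    lines = buf.getvalue().splitlines()
    for i in range(0, len(lines), 4):
        quals = tuple(ord(c) - 33 for c in lines[i + 3])
        reads.append(HairpinRead(lines[i][1:], lines[i + 1], quals))
    return pool, outcomes, reads
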