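"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular outputs are tab-separated with a single header line; FASTQ is
Sanger Phred+33 via Biopython.  The run manifest is JSON and its counts
must reconcile (reads in = accepted + sum of rejections).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .flankprof import ContextTable, EnrichmentProfile
from .hairpin import HairpinRead, ReconstructedMolecule


def read_fastq(path: str | Path) -> Iterator[HairpinRead]:
    """Iterate hairpin reads from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield HairpinRead(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_context_table(table: ContextTable, path: str | Path) -> None:
    df = table.df.copy()
    df.index.name = "context"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_context_table(path: str | Path, k: int | None = None,
                       central_dinucleotide: str = "CG") -> ContextTable:
    df = pd.read_csv(path, sep="\t", index_col="context",
                     dtype={"context": str})
    needed = {"n_total", "n_meth", "level_raw", "level_smoothed"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"context table {path} missing columns: {sorted(missing)}")
    if k is None:
        k = len(str(df.index[0])) // 2 if len(df) else 0
    return ContextTable(k=k, central_dinucleotide=central_dinucleotide, df=df)


def write_enrichment(profile: EnrichmentProfile, path: str | Path) -> None:
    profile.df.to_csv(path, sep="\t", float_format="%.6g")


def write_pfm(pfm: pd.DataFrame, path: str | Path) -> None:
    """Position frequency matrix, logo-tool-compatible (positions x A/C/G/T)."""
    pfm.to_csv(path, sep="\t", float_format="%.6g")


def write_molecule_calls(molecules: Iterable[ReconstructedMolecule],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\toriginal_top_sequence\tstate_top\tstate_bottom"
                 "\tn_pair_mismatches\tqc_pass\n")
        for m in molecules:
            fh.write(f"{m.read_id}\t{m.original_top_sequence}\t{m.state_top}"
                     f"\t{m.state_bottom}\t{m.n_pair_mismatches}\t{int(m.qc_pass)}\n")


def write_manifest(path: str | Path, *, config: Mapping, seed: int,
                   counts: Mapping[str, int], extra: Mapping | None = None) -> None:
    """Run manifest: config snapshot, seed and reconciling stage counts."""
    import methylflank

    payload = {
        "version": methylflank.__version__,
        "seed": seed,
        "config": dict(config),
        "counts": dict(counts),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
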