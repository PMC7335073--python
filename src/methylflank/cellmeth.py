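"""Cellular methylome summaries from per-cytosine call tables.

Consumes post-alignment, Bismark-style cytosine reports (tab-separated:
chromosome, 1-based position of the cytosine on its strand, strand,
methylated count, unmethylated count, context class, trinucleotide) plus a
genome FASTA, and re-implements the bespoke downstream steps used to
compare in-cell methylomes with in-vitro preference profiles:

* a read-level non-conversion filter (discard read ends carrying >= 3
  methylated non-CpG cytosines, evidence of escaped conversion);
* positional clipping constants for paired-end methylation extraction;
* an exact binomial upper-tail test of methylation per cytosine, with
  Benjamini-Hochberg correction across sites;
* conversion-rate QC from reads mapped to an unmethylated spike-in
  control genome (phage lambda);
* depth-filtered (>= 10x by default) aggregation of per-site levels into
  flanking-context tables that share the schema of the in-vitro tables,
  so profile correlations apply directly.

In the aggregated tables each genomic site contributes one observation:
n_total counts sites and n_meth accumulates per-site levels, so level_raw
is the site-weighted mean methylation of the context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from statsmodels.stats.multitest import multipletests

from ._seq import revcomp
from .flankprof import ContextTable, VALID_MOTIFS

#: 5' bases ignored per mate (positional methylation bias at read starts).
FIVE_PRIME_CLIP = {1: 4, 2: 2}
#: 3' bases clipped from every read (questionable base quality).
THREE_PRIME_CLIP = 5

REPORT_COLUMNS = ["chromosome", "position", "strand", "meth_count",
                  "unmeth_count", "context_class", "trinucleotide"]


@dataclass(frozen=True)
class CytosineState:
    """One cytosine observed in a read: methylated or not, CpG or not."""

    methylated: bool
    is_cpg: bool


def nonconversion_read_filter(
    read: Iterable[CytosineState], limit: int = 3
) -> bool:
    """True (keep) unless the read has >= ``limit`` methylated non-CpG cytosines.

    Reads saturated with non-CpG methylation almost certainly escaped
    bisulfite conversion; CpG methylation is ignored by the rule.
    """
    n = sum(1 for c in read if c.methylated and not c.is_cpg)
    return n < limit


def clip_positions(read_index: int) -> int:
    """Number of 5' bases to ignore for read 1 (4) or read 2 (2)."""
    try:
        return FIVE_PRIME_CLIP[read_index]
    except KeyError:
        raise ValueError(f"read_index must be 1 or 2, got {read_index}") from None


def binomial_call(meth_count: int, depth: int, error_rate: float) -> float:
    """Exact upper-tail binomial p-value P(X >= meth_count | depth, error_rate).

    The null is that observed methylated calls arise from non-conversion /
    sequencing error alone at rate ``error_rate``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    if not 0 <= meth_count <= depth:
        raise ValueError("meth_count must be within 0..depth")
    if meth_count == 0:
        return 1.0
    from scipy.stats import binom

    return float(binom.sf(meth_count - 1, depth, error_rate))


def add_binomial_calls(
    records: pd.DataFrame, error_rate: float, fdr: float = 0.05
) -> pd.DataFrame:
    """Attach p_value, q_value (Benjamini-Hochberg) and a significance flag.

    No record is dropped or zeroed: non-significant sites keep their counts
    and p-values for downstream inspection.
    """
    depth = records["meth_count"] + records["unmeth_count"]
    from scipy.stats import binom

    p = binom.sf(records["meth_count"] - 1, depth, error_rate)
    p = np.where(records["meth_count"] == 0, 1.0, p)
    out = records.copy()
    out["p_value"] = p
    if len(out):
        reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
        out["q_value"] = q
        out["significant"] = reject
    else:
        out["q_value"] = np.nan
        out["significant"] = False
    return out


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Load a Bismark-style cytosine report (no header, 7 columns)."""
    df = pd.read_csv(path, sep="\t", header=None, names=REPORT_COLUMNS,
                     comment="#",
                     dtype={"chromosome": str, "strand": str,
                            "context_class": str, "trinucleotide": str})
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{bad.sum()} records with strand outside +/-")
    return df


@dataclass(frozen=True)
class LambdaQC:
    n_calls: int
    conversion_rate: float
    below_bound: bool


def lambda_conversion_qc(
    records: pd.DataFrame, control_chromosomes: Sequence[str],
    bound: float = 0.99,
) -> LambdaQC:
    """Conversion rate from the unmethylated spike-in control genome.

    rate = 1 - sum(meth) / sum(depth) over control cytosines; the control
    genome is fully unmethylated, so every methylated call is a
    non-conversion (or error) event.
    """
    ctl = records[records["chromosome"].isin(control_chromosomes)]
    depth = int((ctl["meth_count"] + ctl["unmeth_count"]).sum())
    if depth == 0:
        raise ZeroDivisionError("no control-genome calls: conversion rate undefined")
    rate = float(1.0 - ctl["meth_count"].sum() / depth)
    return LambdaQC(n_calls=depth, conversion_rate=rate,
                    below_bound=rate < bound)


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(genome), "fasta")}
    return {k: v.upper() for k, v in dict(genome).items()}


def site_context(genome: Mapping[str, str], chromosome: str, position: int,
                 strand: str, k: int) -> tuple[str, str] | None:
    """Strand-oriented (dinucleotide, flank context) at a genomic cytosine.

    ``position`` is 1-based on the forward strand (the G of the pair for
    minus-strand records).  Returns None when the window leaves the contig
    or contains a non-ACGT base.
    """
    seq = genome.get(chromosome)
    if seq is None:
        return None
    p0 = position - 1
    if strand == "+":
        lo, hi = p0 - k, p0 + 2 + k
        if lo < 0 or hi > len(seq):
            return None
        window = seq[lo:hi]
    else:
        lo, hi = p0 - 1 - k, p0 + 1 + k
        if lo < 0 or hi > len(seq):
            return None
        window = revcomp(seq[lo:hi])
    if set(window) - set("ACGT"):
        return None
    if window[k] != "C":
        return None
    return window[k : k + 2], window[:k] + window[k + 2 :]


@dataclass
class GenomicContextSummary:
    """Depth-filtered context aggregation of a cellular methylome."""

    tables: dict[str, ContextTable]   # central dinucleotide -> table
    plus1: pd.DataFrame               # dinucleotide x (+1 base) site-weighted means
    n_sites_used: int
    n_below_depth: int
    n_skipped: int                    # off-contig / N-containing / non-C reference


def genomic_context_summary(
    records: pd.DataFrame,
    genome,
    k: int = 3,
    min_depth: int = 10,
    collapse_strands: bool = False,
) -> GenomicContextSummary:
    """Aggregate per-cytosine calls into flanking-context tables.

    Only sites with depth >= ``min_depth`` contribute.  Each site adds one
    observation with weight 1: its level meth/depth.  With
    ``collapse_strands`` the counts of the two symmetric CpG cytosines are
    summed into the plus-strand site before filtering and aggregation
    (non-CpG sites are never collapsed).
    """
    gen = _load_genome(genome)
    df = records
    if collapse_strands:
        df = _collapse_cpg_strands(df, gen)
    depth = df["meth_count"] + df["unmeth_count"]
    kept = df[depth >= min_depth]
    n_below = len(df) - len(kept)
    agg: dict[str, dict[str, list[float]]] = {d: {} for d in VALID_MOTIFS}
    plus1_acc: dict[tuple[str, str], list[float]] = {}
    n_skipped = 0
    n_used = 0
    for row in kept.itertuples(index=False):
        ctx = site_context(gen, row.chromosome, row.position, row.strand, k)
        if ctx is None:
            n_skipped += 1
            continue
        dinuc, flanks = ctx
        if dinuc not in VALID_MOTIFS:
            n_skipped += 1
            continue
        level = row.meth_count / (row.meth_count + row.unmeth_count)
        agg[dinuc].setdefault(flanks, []).append(level)
        plus1_acc.setdefault((dinuc, flanks[k]), []).append(level)
        n_used += 1
    tables = {}
    for dinuc, ctxmap in agg.items():
        if ctxmap:
            idx = sorted(ctxmap)
            n_sites = np.array([len(ctxmap[c]) for c in idx], dtype=float)
            sums = np.array([sum(ctxmap[c]) for c in idx])
            tdf = pd.DataFrame({"n_total": n_sites.astype(int), "n_meth": sums},
                               index=pd.Index(idx, name="context"))
            tdf["level_raw"] = tdf["n_meth"] / tdf["n_total"]
            tdf["level_smoothed"] = (tdf["n_meth"] + 0.5) / (tdf["n_total"] + 1)
        else:
            tdf = pd.DataFrame(columns=["n_total", "n_meth", "level_raw",
                                        "level_smoothed"])
            tdf.index.name = "context"
        tables[dinuc] = ContextTable(k=k, central_dinucleotide=dinuc, df=tdf)
    plus1 = pd.DataFrame(np.nan, index=pd.Index(list(VALID_MOTIFS), name="dinucleotide"),
                         columns=pd.Index(["A", "C", "G", "T"], name="plus1"))
    for (dinuc, b), levels in plus1_acc.items():
        plus1.loc[dinuc, b] = float(np.mean(levels))
    return GenomicContextSummary(tables=tables, plus1=plus1, n_sites_used=n_used,
                                 n_below_depth=n_below, n_skipped=n_skipped)


def _collapse_cpg_strands(df: pd.DataFrame, genome: Mapping[str, str]) -> pd.DataFrame:
    """Sum symmetric CpG pair counts onto the plus-strand cytosine."""
    rows = []
    minus_cpg = {}
    for row in df.itertuples(index=False):
        seq = genome.get(row.chromosome, "")
        p0 = row.position - 1
        if row.strand == "-" and p0 >= 1 and seq[p0 - 1 : p0 + 1] == "CG":
            # partner plus-strand C sits one base 5' (position - 1)
            minus_cpg[(row.chromosome, row.position - 1)] = row
        else:
            rows.append(row)
    out = []
    for row in rows:
        partner = minus_cpg.pop((row.chromosome, row.position), None)
        if partner is not None:
            row = row._replace(meth_count=row.meth_count + partner.meth_count,
                               unmeth_count=row.unmeth_count + partner.unmeth_count)
        out.append(row)
    # minus-strand CpGs with no plus-strand record survive unchanged
    out.extend(minus_cpg.values())
    return pd.DataFrame(out, columns=df.columns)
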