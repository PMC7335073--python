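"""Flanking-sequence preference statistics.

Each reconstructed molecule contributes up to two *strand events*: the
top-strand target cytosine, and (for CpG targets) the bottom-strand
cytosine.  Every event carries the flanking context read 5'->3' on the
strand bearing the scored cytosine — bottom-strand events therefore use
the reverse-complement window — plus a hard methylated/unmethylated label.

From the event table the module computes the per-context methylation
tables (NNCGNN at k=2, NNNCGNNN at k=3), their CpG/CpA/CpT/CpC splits,
the positional base-enrichment profile among methylated events, position
frequency matrices of the most preferred contexts, event-weighted +1-base
summaries, profile correlations and CpH/CpG specificity ratios.

Two level estimators are kept side by side in every table: the raw
fraction m/n for reporting, and the smoothed (m+0.5)/(n+1) used wherever
a ratio or ranking is taken downstream (never divides by zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import BASES, revcomp
from .config import VALID_MOTIFS, SubstrateLayout
from .hairpin import ReconstructedMolecule

EVENT_COLUMNS = ("context", "dinucleotide", "strand", "methylated")


@dataclass
class ContextTable:
    """Per-context methylation counts and level estimates.

    ``df`` is indexed by the 2k-long context string with columns
    n_total, n_meth, level_raw, level_smoothed.
    """

    k: int
    central_dinucleotide: str
    df: pd.DataFrame

    @property
    def n_events(self) -> int:
        return int(self.df["n_total"].sum())


@dataclass
class EnrichmentProfile:
    """Observed/expected base-composition spread per flank position.

    ``df`` is indexed by signed position (-k..-1, +1..+k) with columns
    raw_sd and normalized; positions where a base is absent among all
    events are NaN and excluded from the normalising maximum.
    """

    df: pd.DataFrame


def strand_events(
    molecules: Iterable[ReconstructedMolecule],
    layout: SubstrateLayout,
) -> pd.DataFrame:
    """Extract scored strand events from QC-passing reconstructed molecules.

    Events whose context window contains a masked base (N) are dropped.
    Bottom-strand events exist only for CpG targets.
    """
    rows = []
    c, f = layout.central_offset, layout.flank_len
    for mol in molecules:
        if not mol.qc_pass:
            continue
        seq = mol.original_top_sequence
        dinuc = seq[c : c + 2]
        ctx = seq[c - f : c] + seq[c + 2 : c + 2 + f]
        if "N" not in ctx and "N" not in dinuc and mol.state_top != "undetermined":
            rows.append((ctx, dinuc, "top", mol.state_top == "methylated"))
        if dinuc == "CG" and mol.state_bottom in ("methylated", "unmethylated"):
            window = revcomp(seq[c - f : c + 2 + f])
            bctx = window[:f] + window[f + 2 :]
            if "N" not in bctx:
                rows.append((bctx, "CG", "bottom", mol.state_bottom == "methylated"))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def events_from_truth(pool, outcomes) -> pd.DataFrame:
    """Strand events straight from simulator ground truth (no sequencing)."""
    by_id = {m.molecule_id: m for m in pool}
    rows = []
    for o in outcomes:
        mol = by_id[o.molecule_id]
        rows.append((o.strand_context, mol.central_motif if o.strand == "top" else "CG",
                     o.strand, o.target_methylated))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _central_window(contexts: pd.Series, k: int) -> pd.Series:
    full = contexts.str.len() // 2
    f = int(full.iloc[0]) if len(contexts) else k
    if k > f:
        raise ValueError(f"k={k} exceeds available flank width {f}")
    return contexts.str[f - k : f] + contexts.str[f : f + k]


def build_context_table(
    events: pd.DataFrame, k: int, central_dinucleotide: str = "CG"
) -> ContextTable:
    """Aggregate strand events into a per-context methylation table."""
    if central_dinucleotide not in VALID_MOTIFS:
        raise ValueError(f"central_dinucleotide must be one of {VALID_MOTIFS}")
    sub = events[events["dinucleotide"] == central_dinucleotide]
    if len(sub):
        ctx = _central_window(sub["context"], k)
        g = sub.assign(context=ctx).groupby("context")["methylated"]
        df = pd.DataFrame({"n_total": g.size(), "n_meth": g.sum().astype(int)})
    else:
        df = pd.DataFrame(columns=["n_total", "n_meth"], dtype=int)
        df.index.name = "context"
    df["level_raw"] = df["n_meth"] / df["n_total"] if len(df) else np.nan
    df["level_smoothed"] = (df["n_meth"] + 0.5) / (df["n_total"] + 1) if len(df) else np.nan
    return ContextTable(k=k, central_dinucleotide=central_dinucleotide,
                        df=df.sort_index())


def split_by_dinucleotide(events: pd.DataFrame, k: int) -> dict[str, ContextTable]:
    """Partition events into the four CpN classes, one table each."""
    return {d: build_context_table(events, k, d) for d in VALID_MOTIFS}


def positional_enrichment(events: pd.DataFrame) -> EnrichmentProfile:
    """Spread of observed/expected base composition among methylated events.

    For each flank position p, ratio(b, p) = frequency of base b at p among
    methylated events divided by its frequency among all events; raw_sd is
    the population standard deviation of the four ratios, and normalized
    scales by the maximum over defined positions.  The expected composition
    is taken from the processed events themselves, which cancels any pool
    synthesis bias.
    """
    if len(events) == 0:
        raise ValueError("no events")
    meth = events[events["methylated"]]
    if len(meth) == 0:
        raise ValueError("no methylated events: enrichment profile undefined")
    f = len(events["context"].iloc[0]) // 2
    positions = list(range(-f, 0)) + list(range(1, f + 1))
    all_arr = np.frombuffer("".join(events["context"]).encode(), dtype="S1").reshape(len(events), 2 * f)
    meth_arr = np.frombuffer("".join(meth["context"]).encode(), dtype="S1").reshape(len(meth), 2 * f)
    raw = []
    for j, _pos in enumerate(positions):
        f_all = np.array([np.mean(all_arr[:, j] == b.encode()) for b in BASES])
        f_meth = np.array([np.mean(meth_arr[:, j] == b.encode()) for b in BASES])
        if np.any(f_all == 0):
            raw.append(np.nan)  # ratio undefined at this position
        else:
            raw.append(float(np.std(f_meth / f_all)))  # population SD (ddof=0)
    raw = np.asarray(raw)
    mx = np.nanmax(raw) if np.any(~np.isnan(raw)) else np.nan
    normalized = raw / mx if mx and mx > 0 else np.zeros_like(raw)
    df = pd.DataFrame({"raw_sd": raw, "normalized": normalized},
                      index=pd.Index(positions, name="position"))
    return EnrichmentProfile(df=df)


def top_site_matrix(
    table: ContextTable, top_k: int, min_coverage: int = 10
) -> pd.DataFrame:
    """Position frequency matrix of the ``top_k`` most preferred contexts.

    Contexts are ordered by raw level descending, ties broken
    lexicographically; each of the top contexts contributes unweighted.
    Returns a (position x base) frequency table whose rows sum to 1.
    """
    eligible = table.df[table.df["n_total"] >= min_coverage]
    if top_k < 1 or top_k > len(eligible):
        raise ValueError(f"top_k={top_k} outside 1..{len(eligible)} eligible rows")
    # primary: level descending; secondary: context lexicographic (deterministic)
    order = eligible.iloc[np.lexsort(
        (eligible.index.to_numpy(), -eligible["level_raw"].to_numpy()))]
    top = order.index[:top_k]
    k = table.k
    positions = list(range(-k, 0)) + list(range(1, k + 1))
    mat = np.zeros((2 * k, 4))
    for ctx in top:
        for j, b in enumerate(ctx):
            mat[j, BASES.index(b)] += 1
    mat /= top_k
    return pd.DataFrame(mat, index=pd.Index(positions, name="position"),
                        columns=list(BASES))


def correlate_tables(
    t1: ContextTable, t2: ContextTable, min_coverage: int = 10,
    estimator: str = "level_raw",
) -> tuple[float, int]:
    """Pearson correlation of per-context levels over shared covered rows.

    Returns (r, number of shared rows).  Raises on fewer than 3 shared rows
    or zero variance in either table.
    """
    j = t1.df[["n_total", estimator]].join(
        t2.df[["n_total", estimator]], how="inner", lsuffix="_1", rsuffix="_2")
    j = j[(j["n_total_1"] >= min_coverage) & (j["n_total_2"] >= min_coverage)]
    if len(j) < 3:
        raise ValueError(f"only {len(j)} shared contexts meet coverage; need >= 3")
    x = j[f"{estimator}_1"].to_numpy(float)
    y = j[f"{estimator}_2"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r), len(j)


def plus1_summary(tables: Mapping[str, ContextTable]) -> pd.DataFrame:
    """Event-weighted mean methylation by (central dinucleotide, +1 base).

    The +1 base is the first flank position 3' of the target dinucleotide.
    Cells without events are NaN.
    """
    out = pd.DataFrame(np.nan, index=pd.Index(list(VALID_MOTIFS), name="dinucleotide"),
                       columns=pd.Index(list(BASES), name="plus1"))
    for dinuc, table in tables.items():
        if len(table.df) == 0:
            continue
        plus1 = table.df.index.str[table.k]
        g = table.df.groupby(plus1)[["n_total", "n_meth"]].sum()
        for b, row in g.iterrows():
            if row["n_total"] > 0:
                out.loc[dinuc, b] = row["n_meth"] / row["n_total"]
    return out


@dataclass
class SpecificityRatios:
    """Per-context CpH/CpG level ratios (smoothed) and their medians."""

    ratios: dict[str, pd.Series]   # "CA/CG", "CT/CG" -> context -> ratio
    medians: dict[str, float]
    n_skipped: dict[str, int]      # contexts missing from a counterpart table


def cpn_specificity(tables: Mapping[str, ContextTable]) -> SpecificityRatios:
    """CpA/CpG and CpT/CpG specificity per flanking context.

    Ratios use smoothed levels on the contexts shared between the CpH table
    and the CpG table; missing counterparts are skipped and counted.
    """
    cg = tables["CG"].df["level_smoothed"]
    ratios, medians, skipped = {}, {}, {}
    for h in ("CA", "CT"):
        if h not in tables or len(tables[h].df) == 0:
            continue
        lh = tables[h].df["level_smoothed"]
        shared = lh.index.intersection(cg.index)
        key = f"{h}/CG"
        ratios[key] = (lh.loc[shared] / cg.loc[shared]).rename(key)
        medians[key] = float(ratios[key].median()) if len(shared) else float("nan")
        skipped[key] = (len(lh) - len(shared)) + (len(cg) - len(shared))
    return SpecificityRatios(ratios=ratios, medians=medians, n_skipped=skipped)
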