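"""Enzyme-versus-enzyme preference comparison.

The central statistic is the normalized preference ratio between two
enzymes (historically DNMT3B over DNMT3A, the "B/A preference"): each
enzyme's smoothed per-context level profile is divided by its own mean —
making the ratio invariant to overall activity and exposure differences
between experiments — and the two normalized profiles are divided
context by context.  Downstream: deterministic rankings (rank 1 = most
preferred), binning of the ratio by similarity to a reference motif such
as the human satellite-II consensus flanks (ATT-CG-ATG), and a
strand-resolved rank analysis of CpG sites in repeat consensus
sequences, where only the more preferred strand of each site counts
because maintenance methylation would complete a hemimethylated site
regardless of which strand was methylated first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import revcomp
from .flankprof import ContextTable


@dataclass
class RatioProfile:
    """Per-context normalized preference ratio R(s) = norm_b(s) / norm_a(s)."""

    ratio: pd.Series       # context -> R(s), finite and > 0
    normalized_b: pd.Series
    normalized_a: pd.Series


def preference_ratio(
    table_b: ContextTable, table_a: ContextTable, min_coverage: int = 10
) -> RatioProfile:
    """Normalized per-context preference of enzyme B relative to enzyme A.

    Uses smoothed levels (never zero), restricted to contexts covered at
    ``min_coverage`` in both tables; each profile is normalized to mean 1
    over the shared set before division.
    """
    if table_b.k != table_a.k or table_b.central_dinucleotide != table_a.central_dinucleotide:
        raise ValueError("tables differ in half-width or central dinucleotide")
    b, a = table_b.df, table_a.df
    shared = b.index[b["n_total"] >= min_coverage].intersection(
        a.index[a["n_total"] >= min_coverage])
    if len(shared) == 0:
        raise ValueError("no shared contexts meet the coverage threshold")
    nb = b.loc[shared, "level_smoothed"]
    na = a.loc[shared, "level_smoothed"]
    nb = nb / nb.mean()
    na = na / na.mean()
    return RatioProfile(ratio=(nb / na).rename("ratio"),
                        normalized_b=nb.rename("normalized_b"),
                        normalized_a=na.rename("normalized_a"))


def rank_profile(values: pd.Series | RatioProfile | ContextTable) -> pd.Series:
    """Deterministic ranking, rank 1 = most preferred (largest value).

    Ties are broken lexicographically by context.  Accepts a raw series, a
    :class:`RatioProfile` (ranks its ratio) or a :class:`ContextTable`
    (ranks its smoothed levels).
    """
    if isinstance(values, RatioProfile):
        values = values.ratio
    elif isinstance(values, ContextTable):
        values = values.df["level_smoothed"]
    if len(values) == 0:
        raise ValueError("empty profile")
    order = np.lexsort((values.index.to_numpy(), -values.to_numpy(float)))
    ranks = pd.Series(0, index=values.index, dtype=int, name="rank")
    ranks.iloc[order] = np.arange(1, len(values) + 1)
    return ranks


def similarity_bins(profile: RatioProfile | pd.Series, reference_context: str) -> pd.DataFrame:
    """Bin the ratio profile by similarity to a reference NNNCGNNN site.

    ``reference_context`` is the 8-mer with the central CG (e.g. the
    satellite-II consensus ATTCGATG); similarity counts matches over the 6
    flank positions only — the CG matches every context by construction.
    Returns a table indexed by bin 0..6 with columns count, median, q1, q3.
    """
    if isinstance(profile, RatioProfile):
        profile = profile.ratio
    if len(reference_context) != 8 or reference_context[3:5] != "CG":
        raise ValueError("reference must be an 8-mer NNNCGNNN with central CG")
    ref = reference_context[:3] + reference_context[5:]
    contexts = profile.index.to_numpy()
    if not len(contexts) or len(contexts[0]) != 6:
        raise ValueError("profile must be over 6-character (k=3) flank contexts")
    arr = np.frombuffer("".join(contexts).encode(), dtype="S1").reshape(len(contexts), 6)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    matches = (arr == ref_arr).sum(axis=1)
    rows = []
    vals = profile.to_numpy(float)
    for b in range(7):
        sel = vals[matches == b]
        if len(sel):
            rows.append((b, len(sel), float(np.median(sel)),
                         float(np.percentile(sel, 25)), float(np.percentile(sel, 75))))
        else:
            rows.append((b, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bin", "count", "median", "q1", "q3"]).set_index("bin")


@dataclass
class RepeatSiteReport:
    """Strand-resolved preference ranks of every CpG site in a sequence set.

    ``sites`` has one row per forward-strand CpG with the 1-based position
    of the C, both strand contexts and each enzyme's chosen (better) rank;
    ``median_rank_a``/``b`` summarize the distributions and
    ``median_rank_ratio`` = median_A / median_B, so a high value means the
    sites rank better (smaller) under enzyme B.
    """

    sites: pd.DataFrame
    n_edge_skipped: int
    median_rank_a: float
    median_rank_b: float

    @property
    def median_rank_ratio(self) -> float:
        return self.median_rank_a / self.median_rank_b


def _load_sequences(sequences) -> dict[str, str]:
    if isinstance(sequences, (str, Path)):
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(sequences), "fasta")}
    return {k: v.upper() for k, v in dict(sequences).items()}


def repeat_rank_analysis(
    sequences,
    ranks_a: pd.Series,
    ranks_b: pd.Series,
    circular: bool = False,
) -> RepeatSiteReport:
    """Rank every CpG site of repeat sequences under two enzyme orderings.

    ``sequences`` is a FASTA path or a name->sequence mapping; rank tables
    must be over k=3 CG contexts (6-character flanks).  For each
    forward-strand CpG the NNNCGNNN context is read on both strands (the
    reverse-strand context is the reverse complement window) and, per
    enzyme, the better (smaller) of the two strand ranks is kept.  Sites
    within 3 bases of a sequence end are skipped and counted unless
    ``circular`` wraps the flanks around (satellite consensus monomers).
    """
    seqs = _load_sequences(sequences)
    rows = []
    n_edge = 0
    for name, seq in seqs.items():
        n = len(seq)
        scan = seq + seq[:1] if circular else seq
        for i in range(len(scan) - 1):
            if scan[i : i + 2] != "CG":
                continue
            if circular:
                window = "".join(seq[(i + d) % n] for d in range(-3, 5))
            else:
                if i < 3 or i + 5 > n:
                    n_edge += 1
                    continue
                window = seq[i - 3 : i + 5]
            fwd = window[:3] + window[5:]
            rwindow = revcomp(window)
            rev = rwindow[:3] + rwindow[5:]
            try:
                ra = int(min(ranks_a[fwd], ranks_a[rev]))
                rb = int(min(ranks_b[fwd], ranks_b[rev]))
            except KeyError as exc:
                raise KeyError(f"context {exc} missing from rank table") from exc
            rows.append((name, i + 1, fwd, rev, ra, rb))
    sites = pd.DataFrame(rows, columns=["sequence", "position", "context_fwd",
                                        "context_rev", "rank_a", "rank_b"])
    med_a = float(sites["rank_a"].median()) if len(sites) else float("nan")
    med_b = float(sites["rank_b"].median()) if len(sites) else float("nan")
    return RepeatSiteReport(sites=sites, n_edge_skipped=n_edge,
                            median_rank_a=med_a, median_rank_b=med_b)
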