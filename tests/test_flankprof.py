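"""Context tables, enrichment profiles, PFMs, correlations and CpN ratios
checked against independent brute-force oracles."""

from __future__ import annotations

from collections import defaultdict
from itertools import product

import numpy as np
import pandas as pd
import pytest

from methylflank import (
    PreferenceModel,
    build_context_table,
    correlate_tables,
    cpn_specificity,
    generate_pool,
    plus1_summary,
    positional_enrichment,
    simulate_methylation,
    split_by_dinucleotide,
    top_site_matrix,
)
from methylflank.flankprof import EVENT_COLUMNS, ContextTable, events_from_truth


def _events(rows):
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _table_from_levels(levels: dict[str, float], n_total: int = 20,
                       k: int = 1, dinuc: str = "CG") -> ContextTable:
    df = pd.DataFrame({
        "n_total": n_total,
        "n_meth": [levels[c] * n_total for c in levels],
        "level_raw": list(levels.values()),
        "level_smoothed": [(levels[c] * n_total + 0.5) / (n_total + 1)
                           for c in levels],
    }, index=pd.Index(list(levels), name="context"))
    return ContextTable(k=k, central_dinucleotide=dinuc, df=df)


# ------------------------------------------------------------ context table

def test_single_event_row():
    t = build_context_table(_events([("ACGT", "CG", "top", True)]), k=2)
    row = t.df.loc["ACGT"]
    assert row["n_total"] == 1 and row["n_meth"] == 1
    assert row["level_raw"] == 1.0
    assert row["level_smoothed"] == pytest.approx(1.5 / 2)


def test_context_table_matches_bruteforce_groupby():
    """Aggregation equals an independent dict-based group-by over events."""
    rng = np.random.default_rng(0)
    pool = generate_pool(400, 3, "CG", seed=1)
    model = PreferenceModel.random_lookup(2, rng)
    outcomes = simulate_methylation(pool, model, seed=2)
    events = events_from_truth(pool, outcomes)
    for k in (1, 2, 3):
        table = build_context_table(events, k=k)
        oracle: dict[str, list[int]] = defaultdict(lambda: [0, 0])
        for o in outcomes:
            ctx = o.strand_context[3 - k : 3] + o.strand_context[3 : 3 + k]
            oracle[ctx][0] += 1
            oracle[ctx][1] += int(o.target_methylated)
        assert set(table.df.index) == set(oracle)
        for ctx, (n, m) in oracle.items():
            row = table.df.loc[ctx]
            assert (row["n_total"], row["n_meth"]) == (n, m)
            assert row["level_raw"] == pytest.approx(m / n)
            assert row["level_smoothed"] == pytest.approx((m + 0.5) / (n + 1))
    assert table.n_events == len(outcomes)


def test_k_exceeding_flank_errors():
    events = _events([("ACGT", "CG", "top", True)])
    with pytest.raises(ValueError):
        build_context_table(events, k=3)


def test_split_partitions_and_matches_subsets():
    rng = np.random.default_rng(3)
    rows = []
    for _ in range(300):
        ctx = "".join(rng.choice(list("ACGT"), 4))
        dinuc = rng.choice(["CG", "CA", "CT", "CC"])
        rows.append((ctx, dinuc, "top", bool(rng.random() < 0.4)))
    events = _events(rows)
    tables = split_by_dinucleotide(events, k=2)
    assert sum(t.n_events for t in tables.values()) == len(events)
    for d, t in tables.items():
        sub = build_context_table(events[events["dinucleotide"] == d], k=2, central_dinucleotide=d)
        pd.testing.assert_frame_equal(t.df, sub.df)


def test_cg_only_pool_leaves_cph_tables_empty():
    events = _events([("ACGT", "CG", "top", True)] * 5)
    tables = split_by_dinucleotide(events, k=2)
    assert tables["CA"].n_events == tables["CT"].n_events == tables["CC"].n_events == 0


# -------------------------------------------------------------- enrichment

def test_enrichment_peak_forced_at_plus1():
    """Methylated events all carry G at +1 while the pool is uniform."""
    rng = np.random.default_rng(4)
    rows = []
    for _ in range(2000):
        ctx = "".join(rng.choice(list("ACGT"), 6))
        meth = ctx[3] == "G"
        rows.append((ctx, "CG", "top", meth))
    prof = positional_enrichment(_events(rows))
    assert prof.df.loc[1, "normalized"] == 1.0
    assert prof.df["normalized"].idxmax() == 1
    assert list(prof.df.index) == [-3, -2, -1, 1, 2, 3]


def test_enrichment_null_below_permutation_99th_percentile():
    """Sequence-independent methylation: observed spread within the
    label-permutation null at every position."""
    rng = np.random.default_rng(5)
    n = 4000
    ctxs = ["".join(c) for c in rng.choice(list("ACGT"), (n, 4))]
    labels = rng.random(n) < 0.3
    events = _events([(c, "CG", "top", bool(m)) for c, m in zip(ctxs, labels)])
    observed = positional_enrichment(events).df["raw_sd"].to_numpy()
    null = np.empty((100, 4))
    for i in range(100):
        perm = rng.permutation(labels)
        ev = _events([(c, "CG", "top", bool(m)) for c, m in zip(ctxs, perm)])
        null[i] = positional_enrichment(ev).df["raw_sd"].to_numpy()
    q99 = np.percentile(null, 99, axis=0)
    assert np.all(observed <= q99)


def test_enrichment_requires_methylated_events():
    events = _events([("ACGT", "CG", "top", False)] * 5)
    with pytest.raises(ValueError):
        positional_enrichment(events)


# ---------------------------------------------------------------- top sites

def test_top1_matrix_is_one_hot():
    t = _table_from_levels({"AA": 0.9, "AC": 0.5, "GT": 0.1})
    pfm = top_site_matrix(t, top_k=1, min_coverage=1)
    assert pfm.loc[-1, "A"] == 1.0 and pfm.loc[1, "A"] == 1.0
    assert np.allclose(pfm.to_numpy().sum(axis=1), 1.0)


def test_full_uniform_table_gives_quarter_frequencies():
    """Taking every context of a complete table reproduces the exact base
    composition of the context universe: 1/4 everywhere."""
    levels = {"".join(c): 0.5 for c in product("ACGT", repeat=4)}
    t = _table_from_levels(levels, k=2)
    pfm = top_site_matrix(t, top_k=len(levels), min_coverage=1)
    assert np.allclose(pfm.to_numpy(), 0.25)


def test_top_k_bounds_checked():
    t = _table_from_levels({"AA": 0.9, "AC": 0.5})
    with pytest.raises(ValueError):
        top_site_matrix(t, top_k=3, min_coverage=1)


def test_tie_break_is_lexicographic():
    t = _table_from_levels({"TT": 0.5, "AA": 0.5, "CC": 0.9})
    pfm = top_site_matrix(t, top_k=2, min_coverage=1)
    # CC first (highest), then AA before TT on the tie
    assert pfm.loc[-1, "C"] == 0.5 and pfm.loc[-1, "A"] == 0.5


# ------------------------------------------------------------- correlation

def test_correlation_analytic_cases():
    t1 = _table_from_levels({"AA": 1, "AC": 2, "AG": 3})
    assert correlate_tables(t1, t1, min_coverage=1)[0] == pytest.approx(1.0)

    t2 = _table_from_levels({"AA": -1 + 5, "AC": -2 + 5, "AG": -3 + 5})
    assert correlate_tables(t1, t2, min_coverage=1)[0] == pytest.approx(-1.0)

    t3 = _table_from_levels({"AA": 2, "AC": 4, "AG": 7})
    r, n = correlate_tables(t1, t3, min_coverage=1)
    assert n == 3
    # closed form: r = sum(dx*dy)/sqrt(sum(dx^2)*sum(dy^2)) = 5/sqrt(2*114/9)
    assert r == pytest.approx(5 / (2 * 114 / 9) ** 0.5, abs=1e-12)
    assert r == pytest.approx(0.993399, abs=5e-7)


def test_correlation_error_cases():
    t1 = _table_from_levels({"AA": 1, "AC": 2, "AG": 3})
    flat = _table_from_levels({"AA": 1, "AC": 1, "AG": 1})
    with pytest.raises(ValueError):
        correlate_tables(t1, flat, min_coverage=1)
    t_small = _table_from_levels({"AA": 1, "AC": 2})
    with pytest.raises(ValueError):
        correlate_tables(t1, t_small, min_coverage=1)
    # symmetry and scale/shift invariance
    t4 = _table_from_levels({"AA": 0.2, "AC": 0.9, "AG": 0.4})
    r_ab = correlate_tables(t1, t4, min_coverage=1)[0]
    r_ba = correlate_tables(t4, t1, min_coverage=1)[0]
    assert r_ab == pytest.approx(r_ba)
    t5 = _table_from_levels({"AA": 10 * 0.2 + 3, "AC": 10 * 0.9 + 3, "AG": 10 * 0.4 + 3})
    assert correlate_tables(t1, t5, min_coverage=1)[0] == pytest.approx(r_ab)


# ------------------------------------------------------------- +1 summary

def test_plus1_summary_matches_bruteforce():
    rng = np.random.default_rng(7)
    rows = []
    for _ in range(500):
        ctx = "".join(rng.choice(list("ACGT"), 2))
        dinuc = rng.choice(["CG", "CA"])
        rows.append((ctx, dinuc, "top", bool(rng.random() < 0.5)))
    events = _events(rows)
    out = plus1_summary(split_by_dinucleotide(events, k=1))
    oracle: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for ctx, dinuc, _s, m in rows:
        oracle[(dinuc, ctx[1])][0] += 1
        oracle[(dinuc, ctx[1])][1] += int(m)
    for (dinuc, b), (n, m) in oracle.items():
        assert out.loc[dinuc, b] == pytest.approx(m / n)
    assert out.loc["CT"].isna().all()  # no CpT events at all


def test_plus1_all_methylated_is_one():
    events = _events([("AG", "CG", "top", True), ("CT", "CG", "top", True)])
    out = plus1_summary(split_by_dinucleotide(events, k=1))
    assert out.loc["CG", "G"] == 1.0 and out.loc["CG", "T"] == 1.0


def test_plus1_matches_marginalized_context_table():
    rng = np.random.default_rng(8)
    rows = [("".join(rng.choice(list("ACGT"), 4)), "CG", "top",
             bool(rng.random() < 0.4)) for _ in range(400)]
    events = _events(rows)
    out = plus1_summary(split_by_dinucleotide(events, k=2))
    t = build_context_table(events, k=2)
    plus1 = t.df.index.str[2]
    marg = t.df.groupby(plus1)[["n_total", "n_meth"]].sum()
    for b, row in marg.iterrows():
        assert out.loc["CG", b] == pytest.approx(row["n_meth"] / row["n_total"])


# --------------------------------------------------------- CpN specificity

def test_cpn_ratio_trivial_cases():
    cg = _table_from_levels({"AA": 0.4, "AC": 0.8})
    same = cpn_specificity({"CG": cg, "CA": cg})
    assert np.allclose(same.ratios["CA/CG"], 1.0)
    assert same.medians["CA/CG"] == pytest.approx(1.0)

    half_df = cg.df.copy()
    half_df["level_smoothed"] = cg.df["level_smoothed"] / 2
    half = ContextTable(k=1, central_dinucleotide="CA", df=half_df)
    res = cpn_specificity({"CG": cg, "CA": half})
    assert np.allclose(res.ratios["CA/CG"], 0.5)


def test_cpn_ratio_recovers_simulated_specificity():
    """CpA rate = 0.3 x CpG rate: median smoothed ratio within 10%."""
    pool_cg = generate_pool(6000, 2, "CG", seed=10)
    pool_ca = generate_pool(6000, 2, "CA", seed=11)
    m_cg = PreferenceModel.constant(0.5)
    m_ca = PreferenceModel.constant(0.15)
    ev = pd.concat([
        events_from_truth(pool_cg, simulate_methylation(pool_cg, m_cg, 12)),
        events_from_truth(pool_ca, simulate_methylation(pool_ca, m_ca, 13)),
    ], ignore_index=True)
    res = cpn_specificity(split_by_dinucleotide(ev, k=2))
    assert res.medians["CA/CG"] == pytest.approx(0.3, rel=0.10)
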