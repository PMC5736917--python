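import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiorec.genome import make_genome_layout
from meiorec.hotspots import (
    call_sites,
    classify_overlap,
    density_vs_size,
    false_call_probability,
    gc_correlation,
    intergenic_enrichment,
    merge_spots,
    normalize_signals,
    positional_profile,
    region_depletion_test,
    scale_activities,
)
from meiorec.simulate import hotspot_landscape, simulate_probe_arrays


def _probe_frame(ratios_by_rep, chrom="chrA"):
    """Build a probe table with given per-replicate log2 ratios."""
    n = len(next(iter(ratios_by_rep.values())))
    df = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(1, n + 1) * 1000,
            "end": np.arange(1, n + 1) * 1000 + 59,
            "context": "intragenic",
        }
    )
    for k, vals in ratios_by_rep.items():
        df[f"rep{k}"] = vals
    return df


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_equal_channels_normalize_to_zero_ratio():
    rng = np.random.default_rng(0)
    s = rng.uniform(0.5, 2.0, 50)
    df = _probe_frame({1: np.zeros(50)})
    df["sig1"], df["ctl1"] = s, s.copy()
    out = normalize_signals(df)
    np.testing.assert_allclose(out["rep1"], 0.0, atol=1e-12)


def test_normalization_is_scale_invariant_and_sums_match():
    rng = np.random.default_rng(1)
    s = rng.uniform(0.1, 5.0, 100)
    c = rng.uniform(0.1, 5.0, 100)
    df = _probe_frame({1: np.zeros(100)})
    df["sig1"], df["ctl1"] = s, c
    out1 = normalize_signals(df)
    df2 = df.copy()
    df2["ctl1"] = c * 10.0
    out2 = normalize_signals(df2)
    np.testing.assert_allclose(out1["rep1"], out2["rep1"], atol=1e-12)
    assert out1["sig1"].sum() == pytest.approx(out1["ctl1"].sum(), rel=1e-9)


def test_all_missing_replicate_rejected():
    df = _probe_frame({1: np.zeros(5)})
    df["sig1"] = np.nan
    df["ctl1"] = np.nan
    with pytest.raises(ValueError, match="no usable probes"):
        normalize_signals(df)


# ---------------------------------------------------------------------------
# scaling and ranking
# ---------------------------------------------------------------------------


def test_minmax_scaling_endpoints():
    df = _probe_frame({1: [-2.0, -1.0, 0.0, 1.0, 2.0]})
    out = scale_activities(df)
    assert out["scaled1"].tolist() == [0.0, 0.25, 0.5, 0.75, 1.0]


def test_integer_ranks_order_and_tie_break():
    out = scale_activities(_probe_frame({1: [0.3, 2.0, -1.0]}))
    assert out["rank1"].tolist() == [2, 1, 3]
    out = scale_activities(_probe_frame({1: [1.0, 1.0, 0.0]}))
    # tie broken by genomic order: earlier probe gets the better rank
    assert out["rank1"].tolist() == [1, 2, 3]


def test_degenerate_replicate_rejected():
    with pytest.raises(ValueError, match="distinct"):
        scale_activities(_probe_frame({1: [1.0, 1.0, 1.0]}))


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def _brute_force_call(df, quantile, category):
    ks = [int(c[4:]) for c in df.columns if c.startswith("rank")]
    keep = set(df.index)
    for k in ks:
        r = df[f"rank{k}"]
        n = int(r.notna().sum())
        n_tail = math.floor(quantile * n)
        if category == "hot":
            sel = set(df.index[(r <= n_tail) & r.notna()])
        else:
            sel = set(df.index[(r > n - n_tail) & r.notna()])
        keep &= sel
    return keep


def test_only_rank_one_probe_is_hot_at_ten_probes():
    rng = np.random.default_rng(2)
    ratios = {k: rng.permutation(10).astype(float) for k in range(1, 5)}
    ranking = scale_activities(_probe_frame(ratios))
    flags = call_sites(ranking, 0.10, "hot")
    hot = set(ranking.index[flags])
    expected = _brute_force_call(ranking, 0.10, "hot")
    assert hot == expected
    assert all(
        (ranking.loc[i, [f"rank{k}" for k in range(1, 5)]] == 1).all() for i in hot
    )


def test_false_call_probability_analytic():
    assert false_call_probability(0.10, 4) == pytest.approx(1e-4)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    n=st.integers(5, 20),
    q=st.floats(0.05, 0.45),
    seed=st.integers(0, 10_000),
    category=st.sampled_from(["hot", "cold"]),
)
def test_calling_matches_brute_force_enumeration(n, q, seed, category):
    rng = np.random.default_rng(seed)
    ratios = {k: rng.normal(size=n) for k in range(1, 4)}
    ranking = scale_activities(_probe_frame(ratios))
    flags = call_sites(ranking, q, category)
    assert set(ranking.index[flags]) == _brute_force_call(ranking, q, category)


def test_calling_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    ratios = {k: rng.normal(size=200) for k in range(1, 5)}
    r1 = scale_activities(_probe_frame(ratios))
    warped = {k: np.exp(v) + k for k, v in ratios.items()}
    r2 = scale_activities(_probe_frame(warped))
    for q in (0.05, 0.10, 0.2):
        for cat in ("hot", "cold"):
            f1 = call_sites(r1, q, cat)
            f2 = call_sites(r2, q, cat)
            assert (f1 == f2).all()


def test_hot_and_cold_flags_are_disjoint():
    rng = np.random.default_rng(4)
    ranking = scale_activities(
        _probe_frame({k: rng.normal(size=300) for k in range(1, 5)})
    )
    for q in (0.1, 0.25, 0.49):
        hot = call_sites(ranking, q, "hot")
        cold = call_sites(ranking, q, "cold")
        assert not (hot & cold).any()


def test_probe_missing_in_one_replicate_never_called():
    ratios = {1: [3.0, 2.0, 1.0, 0.0], 2: [np.nan, 2.0, 1.0, 0.0]}
    ranking = scale_activities(_probe_frame({1: ratios[1]}))
    ranking["rank2"] = [np.nan, 1, 2, 3]
    flags = call_sites(ranking, 0.3, "hot")
    assert not flags.iloc[0]


def test_quantile_bounds_rejected():
    ranking = scale_activities(_probe_frame({1: [1.0, 2.0, 3.0]}))
    for q in (0.0, 0.5, -0.1, 0.9):
        with pytest.raises(ValueError):
            call_sites(ranking, q, "hot")


def test_noiseless_calls_recover_top_decile_of_landscape(small_layout):
    rng = np.random.default_rng(5)
    act = rng.uniform(0.5, 3.0, small_layout.n_probes)
    table = simulate_probe_arrays(small_layout, act, 4, noise_sd=0.0, seed=6)
    ranking = scale_activities(normalize_signals(table))
    flags = call_sites(ranking, 0.10, "hot")
    n_tail = math.floor(0.10 * small_layout.n_probes)
    expected = set(np.argsort(-act, kind="stable")[:n_tail])
    assert set(ranking.index[flags]) == expected


# ---------------------------------------------------------------------------
# spot merging and overlap
# ---------------------------------------------------------------------------


def test_merge_runs_and_chromosome_boundaries():
    ranking = scale_activities(_probe_frame({1: [1.0, 2.0, 3.0, 4.0]}))
    ranking["mean_scaled"] = 0.5
    flags = pd.Series([True, True, False, True], index=ranking.index)
    spots = merge_spots(flags, ranking)
    assert len(spots) == 2
    assert spots["n_probes"].tolist() == [2, 1]
    assert merge_spots(pd.Series([False] * 4, index=ranking.index), ranking).empty
    ranking2 = ranking.copy()
    ranking2.loc[2:, "chrom"] = "chrB"
    flags2 = pd.Series([True, True, True, True], index=ranking2.index)
    assert len(merge_spots(flags2, ranking2)) == 2


def test_merge_respects_max_gap():
    ranking = scale_activities(_probe_frame({1: [1.0, 2.0, 3.0]}))
    ranking["mean_scaled"] = 0.5
    flags = pd.Series([True, True, True], index=ranking.index)
    assert len(merge_spots(flags, ranking, max_gap_bp=100)) == 3
    assert len(merge_spots(flags, ranking, max_gap_bp=2000)) == 1


def _spots(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(
        category="hot", temperature=None, mean_activity=0.5
    )


def test_overlap_identical_and_disjoint_lists():
    a = _spots([("c1", 100, 200), ("c2", 50, 80)])
    ov = classify_overlap({"x": a, "y": a.copy(), "z": a.copy()})
    assert ov.counts["x+y+z"] == 2
    assert ov.fraction_all_three == pytest.approx(1.0)
    b = _spots([("c1", 500, 600)])
    c = _spots([("c1", 900, 950)])
    ov2 = classify_overlap({"x": a, "y": b, "z": c})
    assert ov2.counts["x"] == 2 and ov2.counts["y"] == 1 and ov2.counts["z"] == 1
    assert ov2.counts["x+y+z"] == 0


# ---------------------------------------------------------------------------
# regional analyses
# ---------------------------------------------------------------------------


def _ranking_with_activity(layout, activity):
    df = layout.probes.copy()
    df["mean_scaled"] = activity
    return df


def test_profile_flat_and_step(small_layout):
    flat = _ranking_with_activity(small_layout, 0.5)
    prof = positional_profile(flat, small_layout, "telomere")
    assert np.allclose(prof["mean_activity"].dropna(), 0.5)
    mid = (small_layout.probes["start"] + small_layout.probes["end"]) / 2
    lengths = small_layout.chrom_lengths()
    L = small_layout.probes["chrom"].map(lengths)
    d_end = np.minimum(mid, L - mid)
    act = np.where(d_end < 20_000, 0.0, 1.0)
    prof2 = positional_profile(
        _ranking_with_activity(small_layout, act), small_layout, "telomere"
    )
    assert prof2["mean_activity"].iloc[0] == pytest.approx(0.0, abs=0.05)
    assert prof2["mean_activity"].iloc[-1] == pytest.approx(1.0, abs=0.05)


def test_profile_parameter_validation(small_layout):
    flat = _ranking_with_activity(small_layout, 0.5)
    with pytest.raises(ValueError):
        positional_profile(flat, small_layout, "telomere", span_bp=4000, window_bp=5000)
    with pytest.raises(ValueError):
        positional_profile(flat, small_layout, "telomere", window_bp=5000, step_bp=6000)


def test_depletion_null_and_extreme(small_layout):
    probes = small_layout.probes
    rng = np.random.default_rng(7)
    idx = rng.choice(len(probes), 200, replace=False)
    uniform_spots = pd.DataFrame(
        {
            "chrom": probes["chrom"].to_numpy()[idx],
            "start": probes["start"].to_numpy()[idx],
            "end": probes["end"].to_numpy()[idx],
        }
    )
    res = region_depletion_test(uniform_spots, small_layout, probes)
    assert res.p_value > 0.01
    # all spots far from telomeres/centromeres on chr4 interior
    interior = pd.DataFrame(
        {"chrom": "chr4", "start": np.linspace(500_000, 700_000, 120), "end": np.linspace(500_500, 700_500, 120)}
    )
    res2 = region_depletion_test(interior, small_layout, probes)
    assert res2.observed == 0 and res2.depleted and res2.p_value < 0.01


def test_density_correlation_detects_planted_relation(yeast_layout):
    rows = []
    for _, r in yeast_layout.chromosomes.iterrows():
        for x in np.linspace(0.1, 0.9, 30):  # equal count -> density ~ 1/L
            rows.append((r["name"], int(x * r["length"]), int(x * r["length"]) + 100))
    spots = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df, r, p = density_vs_size(spots, yeast_layout)
    assert r < 0 and p < 0.05
    # equal densities: count proportional to length
    rows = []
    for _, c in yeast_layout.chromosomes.iterrows():
        k = int(round(30 * c["length"] / 1e6))
        for x in np.linspace(0.1, 0.9, k):
            rows.append((c["name"], int(x * c["length"]), int(x * c["length"]) + 100))
    df2, r2, p2 = density_vs_size(pd.DataFrame(rows, columns=["chrom", "start", "end"]), yeast_layout)
    assert abs(r2) < 0.5 or p2 > 0.05
    two = make_genome_layout(lengths=[100_000, 200_000], marker_spacing=1000, seed=1)
    with pytest.raises(ValueError):
        density_vs_size(spots, two)


def test_enrichment_null_and_planted(yeast_layout):
    probes = yeast_layout.probes
    rng = np.random.default_rng(8)
    flags = pd.Series(rng.random(len(probes)) < 0.05, index=probes.index)
    df, thr = intergenic_enrichment(flags, probes)
    assert ((df["ratio"] - 1.0).abs() < 0.35).all()
    # plant all hot probes in divergent intergenic regions
    div = probes.index[probes["context"] == "intergenic_divergent"][:200]
    flags2 = pd.Series(False, index=probes.index)
    flags2.loc[div] = True
    df2, thr2 = intergenic_enrichment(flags2, probes)
    row = df2.set_index("context").loc["intergenic_divergent"]
    assert row["ratio"] == df2[df2["context"] != "intergenic_total"]["ratio"].max()
    assert row["p_value"] < 0.003


def test_gc_correlation_cases():
    n = 100
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "c1",
            "start": np.arange(n) * 1000 + 500,
            "end": np.arange(n) * 1000 + 560,
            "context": "intragenic",
        }
    )
    # constant GC: undefined correlation
    seq_const = "ACGT" * (n * 1000 // 4 + 2000)
    probes["mean_scaled"] = np.linspace(0, 1, n)
    res = gc_correlation({"c1": seq_const}, probes)
    assert res.r is None and "zero variance" in res.note
    # GC gradient, activity equal to window GC -> r ~ 1
    rng = np.random.default_rng(9)
    gcs = np.linspace(0.2, 0.8, n + 10)
    seq = "".join(
        "".join(rng.choice(["G", "A"], 1000, p=[g, 1 - g])) for g in gcs
    )
    probes2 = probes.copy()
    # set activity to the planted local GC
    probes2["mean_scaled"] = gcs[(probes["start"] // 1000).to_numpy()]
    res2 = gc_correlation({"c1": seq}, probes2)
    assert res2.r > 0.95 and res2.p_value < 1e-6
    # noisy coupling
    probes3 = probes.copy()
    probes3["mean_scaled"] = 0.5 * gcs[(probes["start"] // 1000).to_numpy()] + 0.1 * rng.normal(
        size=n
    )
    res3 = gc_correlation({"c1": seq}, probes3)
    assert res3.r > 0 and res3.p_value < 0.01
    with pytest.raises(ValueError, match="outside sequence"):
        gc_correlation({"c1": seq[:5000]}, probes2)
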