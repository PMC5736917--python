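"""Spo11 ChIP-chip hotspot analysis.

The pipeline mirrors the experimental analysis of replicate tiling-array
log-ratios:

1. :func:`normalize_signals` — rescale each replicate so the summed signal and
   control intensities match, then form log2(S/C).
2. :func:`scale_activities` — two per-replicate activity scales: a 0-1
   min-max scaled ratio (1 = hottest) and an integer rank 1..N (1 = hottest).
3. :func:`call_sites` — a probe is hot (cold) when it ranks in the top
   (bottom) ``quantile`` of every replicate; with four independent replicates
   at quantile 0.10 the per-probe false-call probability is 1e-4.
4. :func:`merge_spots` — adjacent flagged probes merge into hot/cold spots.

Regional and contextual analyses (telomere/centromere profiles and depletion
tests, hotspot density vs chromosome size, intergenic-class enrichment, GC
correlation) operate on the ranking and spot tables.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PROBE_CONTEXTS, GenomeLayout

PROBE_KEY_COLUMNS = ["probe_id", "chrom", "start", "end", "context"]


def _replicate_indices(df: pd.DataFrame, prefix: str) -> list[int]:
    pat = re.compile(rf"^{prefix}(\d+)$")
    ks = sorted(int(m.group(1)) for c in df.columns if (m := pat.match(c)))
    return ks


def normalize_signals(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize replicate signal/control intensities and form log2 ratios.

    Each replicate's signal (``sigK``) and control (``ctlK``) columns are
    rescaled so that the summed hybridization value over all probes is the
    same (unity) for both channels; the normalized log2(S/C) is stored as
    ``repK``. Tables that already carry ``repK`` ratio columns (and no raw
    intensities) pass through unchanged.
    """
    sig_ks = _replicate_indices(table, "sig")
    if not sig_ks:
        if _replicate_indices(table, "rep"):
            return table.copy()
        raise ValueError("no sigK/ctlK intensity columns and no repK ratio columns")
    out = table.copy()
    for k in sig_ks:
        s = out[f"sig{k}"].astype(float)
        c = out[f"ctl{k}"].astype(float)
        ok = s.notna() & c.notna()
        if not ok.any():
            raise ValueError(f"replicate {k} has no usable probes")
        ssum, csum = s[ok].sum(), c[ok].sum()
        if ssum <= 0 or csum <= 0:
            raise ValueError(f"replicate {k} has non-positive channel sum")
        sn, cn = s / ssum, c / csum
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"rep{k}"] = np.log2(sn / cn)
        out.loc[~ok, f"rep{k}"] = np.nan
        out[f"sig{k}"] = sn
        out[f"ctl{k}"] = cn
    out.attrs["normalized"] = True
    return out


def scale_activities(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate min-max scaled activities and integer ranks.

    ``scaledK`` maps the normalized ratio linearly onto [0, 1] with 1 at the
    hottest probe; ``rankK`` is the integer rank 1..N with 1 the hottest, ties
    broken by genomic order (the earlier probe gets the better rank).
    ``mean_scaled`` averages the scaled values across replicates.
    """
    ks = _replicate_indices(table, "rep")
    if not ks:
        raise ValueError("no repK ratio columns; run normalize_signals first")
    out = table[[c for c in PROBE_KEY_COLUMNS if c in table.columns]].copy()
    n = len(table)
    scaled_cols = []
    for k in ks:
        v = table[f"rep{k}"].to_numpy(dtype=float)
        ok = np.isfinite(v)
        vals = v[ok]
        if np.unique(vals).size < 2:
            raise ValueError(f"replicate {k} has fewer than 2 distinct values")
        lo, hi = vals.min(), vals.max()
        scaled = (v - lo) / (hi - lo)
        scaled[~ok] = np.nan
        out[f"scaled{k}"] = scaled
        # stable sort on (-ratio) keeps genomic (row) order among ties
        key = np.where(ok, -v, np.inf)
        order = np.argsort(key, kind="stable")
        rank = np.empty(n, dtype=float)
        rank[order] = np.arange(1, n + 1)
        rank[~ok] = np.nan
        out[f"rank{k}"] = rank
        scaled_cols.append(f"scaled{k}")
    out["mean_scaled"] = out[scaled_cols].mean(axis=1)
    out.attrs["n_replicates"] = len(ks)
    return out


def false_call_probability(quantile: float, n_replicates: int) -> float:
    """Probability that a probe with independent replicate ranks is called
    hot (or cold): quantile ** n_replicates (1e-4 at 0.10 with 4 replicates)."""
    return float(quantile) ** int(n_replicates)


def call_sites(
    ranking: pd.DataFrame,
    quantile: float = 0.10,
    category: str = "hot",
    replicates_required: int | None = None,
) -> pd.Series:
    """Flag probes ranking in the top (hot) or bottom (cold) tail of every
    replicate.

    A probe is hot when its integer rank is <= floor(quantile*N) in all
    replicates (cold: rank > N - floor(quantile*N)), where N is that
    replicate's non-missing probe count. Probes missing in a required
    replicate are never flagged. ``replicates_required`` relaxes "all" to a
    minimum number of concordant replicates.
    """
    if not (0.0 < quantile < 0.5):
        raise ValueError("quantile must be in (0, 0.5)")
    if category not in ("hot", "cold"):
        raise ValueError("category must be 'hot' or 'cold'")
    ks = _replicate_indices(ranking, "rank")
    if not ks:
        raise ValueError("ranking table lacks rankK columns")
    need = len(ks) if replicates_required is None else int(replicates_required)
    if not (1 <= need <= len(ks)):
        raise ValueError("replicates_required out of range")
    votes = np.zeros(len(ranking), dtype=int)
    thresholds = {}
    for k in ks:
        r = ranking[f"rank{k}"].to_numpy(dtype=float)
        n_k = int(np.isfinite(r).sum())
        n_tail = math.floor(quantile * n_k)
        thresholds[k] = n_tail
        if category == "hot":
            votes += (r <= n_tail) & np.isfinite(r)
        else:
            votes += (r > n_k - n_tail) & np.isfinite(r)
    flags = pd.Series(votes >= need, index=ranking.index, name=category)
    flags.attrs["quantile"] = quantile
    flags.attrs["tail_sizes"] = thresholds
    return flags


def merge_spots(
    flags: pd.Series,
    ranking: pd.DataFrame,
    category: str = "hot",
    temperature: str | None = None,
    max_gap_bp: float | None = None,
) -> pd.DataFrame:
    """Merge maximal runs of flagged probes adjacent in array order on one
    chromosome into single spots.

    By default any run of consecutive flagged probes merges regardless of the
    bp gap between them; ``max_gap_bp`` optionally breaks runs across larger
    genomic gaps.
    """
    f = np.asarray(flags, dtype=bool)
    chrom = ranking["chrom"].to_numpy()
    start = ranking["start"].to_numpy()
    end = ranking["end"].to_numpy()
    pid = ranking["probe_id"].to_numpy()
    act = (
        ranking["mean_scaled"].to_numpy(dtype=float)
        if "mean_scaled" in ranking
        else np.full(len(ranking), np.nan)
    )
    rows = []
    i, n = 0, len(ranking)
    while i < n:
        if not f[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and f[j + 1]
            and chrom[j + 1] == chrom[j]
            and (max_gap_bp is None or start[j + 1] - end[j] - 1 <= max_gap_bp)
        ):
            j += 1
        members = slice(i, j + 1)
        rows.append(
            (
                category,
                temperature,
                chrom[i],
                int(start[i]),
                int(end[j]),
                j - i + 1,
                ",".join(pid[members]),
                float(np.nanmean(act[members])),
            )
        )
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "temperature",
            "chrom",
            "start",
            "end",
            "n_probes",
            "probe_ids",
            "mean_activity",
        ],
    )


@dataclass
class OverlapClasses:
    """Venn classification of spot sets from three conditions.

    ``counts`` maps each of the 7 categories (labels joined by '+') to the
    number of merged overlap components assigned to it; components are
    connected sets of genomically intersecting spots. ``fraction_all_three``
    is the triple-category count divided by the mean per-condition spot count.
    """

    labels: tuple[str, str, str]
    counts: dict[str, int]
    n_union: int
    fraction_all_three: float


def classify_overlap(spots_by_label: Mapping[str, pd.DataFrame]) -> OverlapClasses:
    """Assign spots from three conditions to the 7 Venn overlap categories.

    Spots overlap when their genomic intervals intersect; overlapping spots
    (within or across conditions) form one component labeled by the set of
    conditions it contains.
    """
    labels = tuple(spots_by_label)
    if len(labels) != 3:
        raise ValueError("exactly three spot lists are required")
    nodes = []  # (chrom, start, end, label)
    for lab, df in spots_by_label.items():
        for _, r in df.iterrows():
            nodes.append((r["chrom"], float(r["start"]), float(r["end"]), lab))
    parent = list(range(len(nodes)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    order = sorted(range(len(nodes)), key=lambda i: (nodes[i][0], nodes[i][1]))
    active: list[int] = []
    for i in order:
        chrom, s, e, _ = nodes[i]
        active = [j for j in active if nodes[j][0] == chrom and nodes[j][2] >= s]
        for j in active:
            union(i, j)
        active.append(i)
    comps: dict[int, set[str]] = {}
    for i in range(len(nodes)):
        comps.setdefault(find(i), set()).add(nodes[i][3])
    counts = {
        "+".join(k): 0
        for m in range(1, 4)
        for k in _label_combos(labels, m)
    }
    for labs in comps.values():
        key = "+".join(l for l in labels if l in labs)
        counts[key] += 1
    triple = counts["+".join(labels)]
    mean_per_label = np.mean([len(df) for df in spots_by_label.values()])
    frac = triple / mean_per_label if mean_per_label else float("nan")
    return OverlapClasses(labels, counts, len(comps), float(frac))


def _label_combos(labels, m):
    from itertools import combinations

    for combo in combinations(labels, m):
        yield combo


def positional_profile(
    ranking: pd.DataFrame,
    layout: GenomeLayout,
    anchor: str = "telomere",
    span_bp: float | None = None,
    window_bp: float = 5000.0,
    step_bp: float = 1000.0,
) -> pd.DataFrame:
    """Mean probe activity vs distance from telomeres or centromeres.

    Probe midpoints within ``span_bp`` of any chromosome end (both ends of all
    chromosomes) or of any centromere (both flanks) are pooled; the mean of
    ``mean_scaled`` is taken in a moving window of ``window_bp`` advanced
    ``step_bp`` at a time. Bins with no probes report NaN.
    """
    if anchor not in ("telomere", "centromere"):
        raise ValueError("anchor must be 'telomere' or 'centromere'")
    if span_bp is None:
        span_bp = 100_000.0 if anchor == "telomere" else 50_000.0
    if window_bp > span_bp:
        raise ValueError("window must not exceed span")
    if step_bp > window_bp:
        raise ValueError("step must not exceed window")
    mid = ((ranking["start"] + ranking["end"]) / 2).to_numpy(dtype=float)
    chrom = ranking["chrom"].to_numpy()
    act = ranking["mean_scaled"].to_numpy(dtype=float)
    lengths = layout.chrom_lengths()
    cens = layout.centromeres()
    dists, vals = [], []
    for c, L in lengths.items():
        sel = chrom == c
        if not sel.any():
            continue
        m, a = mid[sel], act[sel]
        if anchor == "telomere":
            for d in (m, L - m):
                keep = d <= span_bp
                dists.append(d[keep])
                vals.append(a[keep])
        else:
            d = np.abs(m - cens[c])
            keep = d <= span_bp
            dists.append(d[keep])
            vals.append(a[keep])
    d = np.concatenate(dists) if dists else np.empty(0)
    v = np.concatenate(vals) if vals else np.empty(0)
    rows = []
    b0 = 0.0
    while b0 + window_bp <= span_bp + 1e-9:
        m = (d >= b0) & (d < b0 + window_bp)
        rows.append(
            (
                b0,
                b0 + window_bp / 2.0,
                float(np.nanmean(v[m])) if m.any() else np.nan,
                int(m.sum()),
            )
        )
        b0 += step_bp
    return pd.DataFrame(rows, columns=["bin_start", "bin_center", "mean_activity", "n_probes"])


@dataclass
class RegionDepletionResult:
    observed: int
    expected: float
    p_value: float | None
    n_spots: int
    fraction_probes_in_region: float
    note: str = ""

    @property
    def depleted(self) -> bool:
        return self.observed < self.expected


def _in_region(pos, chrom, lengths, cens, tel_margin, cen_margin):
    L = np.array([lengths[c] for c in chrom], dtype=float)
    cen = np.array([cens[c] for c in chrom], dtype=float)
    return (pos <= tel_margin) | (pos >= L - tel_margin) | (np.abs(pos - cen) <= cen_margin)


def region_depletion_test(
    spots: pd.DataFrame,
    layout: GenomeLayout,
    probes: pd.DataFrame,
    telomere_margin_bp: float = 50_000.0,
    centromere_margin_bp: float = 25_000.0,
) -> RegionDepletionResult:
    """Observed vs expected spot count near telomeres/centromeres.

    Expected = total spots x (fraction of probes whose midpoint lies within
    the margins), i.e. corrected for probe density; observed counts spot
    midpoints. A 1-df chi-square compares the in/out partition.
    """
    if telomere_margin_bp < 0 or centromere_margin_bp < 0:
        raise ValueError("margins must be >= 0")
    lengths, cens = layout.chrom_lengths(), layout.centromeres()
    pmid = ((probes["start"] + probes["end"]) / 2).to_numpy(dtype=float)
    pin = _in_region(
        pmid, probes["chrom"].to_numpy(), lengths, cens, telomere_margin_bp, centromere_margin_bp
    )
    frac = float(pin.mean()) if len(probes) else 0.0
    n_spots = len(spots)
    if frac == 0.0:
        return RegionDepletionResult(0, 0.0, None, n_spots, 0.0, "no probes in region; test skipped")
    smid = ((spots["start"] + spots["end"]) / 2).to_numpy(dtype=float)
    sin = _in_region(
        smid, spots["chrom"].to_numpy(), lengths, cens, telomere_margin_bp, centromere_margin_bp
    )
    observed = int(sin.sum())
    expected = n_spots * frac
    if n_spots == 0:
        return RegionDepletionResult(0, 0.0, None, 0, frac, "no spots")
    chi = stats.chisquare(
        [observed, n_spots - observed], [expected, n_spots - expected]
    )
    return RegionDepletionResult(observed, float(expected), float(chi.pvalue), n_spots, frac)


def density_vs_size(
    spots: pd.DataFrame, layout: GenomeLayout
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome spot density (per Mb) and its Pearson correlation with
    chromosome length."""
    chroms = layout.chromosomes
    if len(chroms) < 3:
        raise ValueError("at least 3 chromosomes required for a correlation")
    if (chroms["length"] <= 0).any():
        raise ValueError("zero-length chromosome")
    counts = spots.groupby("chrom").size()
    df = chroms[["name", "length"]].copy()
    df["n_spots"] = df["name"].map(counts).fillna(0).astype(int)
    df["density_per_mb"] = df["n_spots"] / (df["length"] / 1e6)
    r, p = stats.pearsonr(df["length"], df["density_per_mb"])
    return df, float(r), float(p)


def intergenic_enrichment(
    flags: pd.Series, table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Observed/expected flagged-probe ratios per gene-context class.

    Expected counts are proportional to each context's frequency among all
    probes; each context gets a 2x2 chi-square against the rest of the array.
    An aggregate "intergenic_total" row pools the three intergenic classes.
    Returns (table, Bonferroni-corrected significance threshold).
    """
    if table["context"].isna().any():
        raise ValueError("every probe must carry a context class")
    f = np.asarray(flags, dtype=bool)
    ctx = table["context"].to_numpy()
    N = len(table)
    n_flag = int(f.sum())
    groups: list[tuple[str, np.ndarray]] = [
        (c, ctx == c) for c in PROBE_CONTEXTS if (ctx == c).any()
    ]
    inter = np.isin(ctx, [c for c in PROBE_CONTEXTS if c.startswith("intergenic")])
    groups.append(("intergenic_total", inter))
    rows = []
    for name, sel in groups:
        n_c = int(sel.sum())
        obs = int((f & sel).sum())
        exp = n_flag * n_c / N
        ratio = obs / exp if exp > 0 else np.nan
        tab = np.array(
            [[obs, n_flag - obs], [n_c - obs, (N - n_flag) - (n_c - obs)]]
        )
        if tab.min() < 0 or n_flag == 0:
            p = np.nan
        else:
            p = stats.chi2_contingency(tab, correction=False)[1]
        rows.append((name, n_c, obs, exp, ratio, p))
    df = pd.DataFrame(
        rows, columns=["context", "n_probes", "observed", "expected", "ratio", "p_value"]
    )
    threshold = alpha / len(df)
    return df, float(threshold)


@dataclass
class GcCorrelationResult:
    r: float | None
    p_value: float | None
    n_probes: int
    note: str = ""


def gc_correlation(
    sequences: Mapping[str, str],
    ranking: pd.DataFrame,
    window_bp: int = 5000,
    step_bp: int = 1000,
) -> GcCorrelationResult:
    """Pearson correlation between windowed GC content and probe activity.

    GC fraction is computed in a sliding window of ``window_bp`` advanced
    ``step_bp`` at a time; each probe takes the GC of the window centered on
    the grid point nearest its midpoint.
    """
    gc_vals = np.empty(len(ranking))
    act = ranking["mean_scaled"].to_numpy(dtype=float)
    cums: dict[str, np.ndarray] = {}
    for c, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        cums[c] = np.concatenate([[0], np.cumsum(is_gc)])
    for i, (_, row) in enumerate(ranking.iterrows()):
        c = row["chrom"]
        if c not in cums:
            raise ValueError(f"no sequence for chromosome {c}")
        n = cums[c].size - 1
        if row["end"] > n:
            raise ValueError(
                f"probe {row.get('probe_id', i)} at {c}:{row['start']}-{row['end']} "
                f"outside sequence of length {n}"
            )
        mid = (row["start"] + row["end"]) / 2.0
        g = int(round(mid / step_bp) * step_bp)
        lo = max(0, g - window_bp // 2)
        hi = min(n, g + window_bp // 2)
        gc_vals[i] = (cums[c][hi] - cums[c][lo]) / max(hi - lo, 1)
    ok = np.isfinite(gc_vals) & np.isfinite(act)
    if ok.sum() < 3 or np.std(gc_vals[ok]) == 0 or np.std(act[ok]) == 0:
        return GcCorrelationResult(None, None, int(ok.sum()), "correlation undefined (zero variance)")
    r, p = stats.pearsonr(gc_vals[ok], act[ok])
    return GcCorrelationResult(float(r), float(p), int(ok.sum()))
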