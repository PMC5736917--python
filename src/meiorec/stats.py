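"""Aggregate statistics over classified recombination events.

Covers the event tally by class, the detectable-conversion correction for
non-crossover events falling between markers, per-tetrad rates, complex-event
fractions, conversion-tract statistics, the crossover-interference
randomization test, and categorical tests on segregation/viability tallies.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import RecombEvent
from .genome import GenomeLayout

CO_CLASSES = (2, 3, 5)  # classes carrying a reciprocal exchange
NCO_CLASSES = (1, 4)  # conversions unassociated with crossovers


def round_half_up(x: float) -> int:
    """Round with ties away from zero, matching printed-table conventions."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class EventTally:
    """Event counts by class (donor-split for classes 1 and 3) for one
    condition."""

    label: str
    n_tetrads: int
    class1_p1: int = 0  # simple NCO, duplication of P1 (W303-1A-like) sequence
    class1_p2: int = 0
    class2: int = 0
    class3_p1: int = 0
    class3_p2: int = 0
    class4: int = 0
    class5: int = 0
    class6: int = 0
    unclassified: int = 0

    @property
    def class1(self) -> int:
        return self.class1_p1 + self.class1_p2

    @property
    def class3(self) -> int:
        return self.class3_p1 + self.class3_p2

    @property
    def total(self) -> int:
        """Total classified events (classes 1-6; unclassified kept apart)."""
        return self.class1 + self.class2 + self.class3 + self.class4 + self.class5 + self.class6

    @property
    def crossovers(self) -> int:
        return self.class2 + self.class3 + self.class5

    @property
    def raw_nco(self) -> int:
        return self.class1 + self.class4

    def percentages(self) -> dict[str, float]:
        """Percent of total per class, printed-table style: whole numbers
        above 1%, one decimal below."""
        tot = self.total
        if tot == 0:
            return {}
        return {
            name: (
                float(round_half_up(100.0 * v / tot))
                if 100.0 * v / tot >= 1.0
                else round(100.0 * v / tot, 1)
            )
            for name, v in [
                ("class1", self.class1),
                ("class2", self.class2),
                ("class3", self.class3),
                ("class4", self.class4),
                ("class5", self.class5),
                ("class6", self.class6),
            ]
        }

    @classmethod
    def from_counts(
        cls,
        label: str,
        n_tetrads: int,
        class1_p1: int,
        class1_p2: int,
        class2: int,
        class3_p1: int,
        class3_p2: int,
        class4: int,
        class5: int,
        class6: int,
    ) -> "EventTally":
        return cls(
            label, n_tetrads, class1_p1, class1_p2, class2, class3_p1, class3_p2,
            class4, class5, class6,
        )

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            ("1 (P1 duplicated)", self.class1_p1),
            ("1 (P2 duplicated)", self.class1_p2),
            ("1 total", self.class1),
            ("2", self.class2),
            ("3 (P1 duplicated)", self.class3_p1),
            ("3 (P2 duplicated)", self.class3_p2),
            ("3 total", self.class3),
            ("4", self.class4),
            ("5", self.class5),
            ("6", self.class6),
            ("unclassified", self.unclassified),
            ("total", self.total),
        ]
        return pd.DataFrame(rows, columns=["class", "count"])


def tally_events(
    events: Sequence[RecombEvent], n_tetrads: int, label: str = ""
) -> EventTally:
    """Count classified events by class; unclassified events are tallied
    separately and never enter classes 1-6."""
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    t = EventTally(label=label, n_tetrads=n_tetrads)
    for e in events:
        if e.cls == 1:
            if e.donor == "P1":
                t.class1_p1 += 1
            else:
                t.class1_p2 += 1
        elif e.cls == 2:
            t.class2 += 1
        elif e.cls == 3:
            if e.donor == "P1":
                t.class3_p1 += 1
            else:
                t.class3_p2 += 1
        elif e.cls == 4:
            t.class4 += 1
        elif e.cls == 5:
            t.class5 += 1
        elif e.cls == 6:
            t.class6 += 1
        else:
            t.unclassified += 1
    return t


@dataclass
class CorrectionResult:
    """Detectable-fraction correction of the non-crossover count.

    ``detectable_fraction`` is the fraction of crossovers with a
    marker-visible conversion tract, f = (c3 + c5) / (c2 + c3 + c5);
    assuming crossover-associated and unassociated tracts are equally
    detectable, the corrected NCO count is (c1 + c4) / f. The reported
    (rounded) chain uses f to 3 decimals, matching printed precision; the
    ``*_exact`` attributes keep full precision.
    """

    label: str
    detectable_fraction: float  # rounded to 3 decimals
    detectable_fraction_exact: float
    raw_nco: int
    corrected_nco: int
    corrected_nco_exact: float
    corrected_nco_per_tetrad: int
    co_per_tetrad: int
    combined_per_tetrad: int


def conversion_correction(tally: EventTally) -> CorrectionResult:
    """Correct the non-crossover conversion count for tracts falling between
    markers, using the crossover-conversion detectable fraction."""
    co = tally.crossovers
    if co == 0:
        raise ValueError("no crossovers; detectable fraction undefined")
    f_exact = (tally.class3 + tally.class5) / co
    f = round(f_exact, 3)
    raw = tally.raw_nco
    corrected_exact = raw / f_exact
    corrected = round_half_up(raw / f)
    per_tet = round_half_up(raw / f / tally.n_tetrads)
    co_pt = round_half_up(co / tally.n_tetrads)
    return CorrectionResult(
        label=tally.label,
        detectable_fraction=f,
        detectable_fraction_exact=f_exact,
        raw_nco=raw,
        corrected_nco=corrected,
        corrected_nco_exact=corrected_exact,
        corrected_nco_per_tetrad=per_tet,
        co_per_tetrad=co_pt,
        combined_per_tetrad=per_tet + co_pt,
    )


@dataclass
class PerTetradSummary:
    label: str
    n_tetrads: int
    co_per_tetrad: float
    nco_per_tetrad: float
    co_per_tetrad_rounded: int
    nco_per_tetrad_rounded: int
    co_range: tuple[int, int] | None = None


def per_tetrad_summary(
    tally: EventTally, events: Sequence[RecombEvent] | None = None
) -> PerTetradSummary:
    """Crossovers and raw non-crossovers per tetrad; when events carrying
    tetrad ids are supplied, the per-tetrad crossover range is included."""
    co = tally.crossovers / tally.n_tetrads
    nco = tally.raw_nco / tally.n_tetrads
    rng = None
    if events:
        per = {}
        for e in events:
            if e.cls in CO_CLASSES:
                per[e.tetrad_id] = per.get(e.tetrad_id, 0) + 1
        if per:
            rng = (min(per.values()), max(per.values()))
    return PerTetradSummary(
        tally.label, tally.n_tetrads, co, nco, round_half_up(co), round_half_up(nco), rng
    )


def complex_fraction(tally: EventTally) -> dict[str, float]:
    """Fraction of conversion-bearing events that are complex.

    Returns the overall percentage (classes 4+5 over 1+3+4+5, one decimal)
    plus the per-association ratios class4/class1 and class5/class3.
    """
    denom = tally.class1 + tally.class3 + tally.class4 + tally.class5
    if denom == 0:
        raise ValueError("no conversion-bearing events")
    pct = round(100.0 * (tally.class4 + tally.class5) / denom, 1)
    return {
        "percent_complex": pct,
        "ratio_no_co": tally.class4 / tally.class1 if tally.class1 else float("nan"),
        "ratio_with_co": tally.class5 / tally.class3 if tally.class3 else float("nan"),
    }


@dataclass
class TractStatistics:
    median_co_associated_bp: float | None
    median_unassociated_bp: float | None
    n_co_associated: int
    n_unassociated: int
    percent_genome_converted: float


def tract_statistics(
    events: Sequence[RecombEvent], genome_size: float, n_tetrads: int
) -> TractStatistics:
    """Median conversion-tract lengths and the percent of the genome converted.

    Lengths use midpoint-extended tract bounds. The converted percentage sums
    tract lengths over all conversion-bearing events (within-tetrad overlaps
    on a chromosome counted once) and divides by genome_size x n_tetrads.
    """
    if genome_size <= 0 or n_tetrads < 1:
        raise ValueError("genome_size and n_tetrads must be positive")
    co_lens, nco_lens = [], []
    by_tetrad: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for e in events:
        L = e.tract_length
        if L is None:
            continue
        if e.cls in (3, 5):
            co_lens.append(L)
        elif e.cls in (1, 4):
            nco_lens.append(L)
        if e.cls in (1, 3, 4, 5, 6):
            by_tetrad.setdefault((e.tetrad_id, e.chrom), []).append((e.ext_start, e.ext_end))
    total = 0.0
    for ivs in by_tetrad.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, ee in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, ee)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, ee
        total += cur_e - cur_s
    return TractStatistics(
        median_co_associated_bp=float(np.median(co_lens)) if co_lens else None,
        median_unassociated_bp=float(np.median(nco_lens)) if nco_lens else None,
        n_co_associated=len(co_lens),
        n_unassociated=len(nco_lens),
        percent_genome_converted=100.0 * total / (genome_size * n_tetrads),
    )


@dataclass
class InterferenceResult:
    """Randomization test of crossover interference.

    ``observed_median`` is the median over all same-chromosome adjacent
    crossover gaps pooled across tetrads; each simulation redraws the same
    per-tetrad crossover counts uniformly over the genome (chromosome chosen
    proportional to length) and the expected median is the median of the
    simulated medians. ``p_value`` is a one-sided rank-sum of the observed
    gaps against the pooled simulated gaps (alternative: observed larger,
    i.e. interference).
    """

    observed_median: float
    expected_median: float
    p_value: float
    n_sims: int
    n_gaps: int
    sim_medians: np.ndarray = field(repr=False)


def _pooled_gaps(df: pd.DataFrame) -> np.ndarray:
    gaps = []
    for (_, _), grp in df.groupby(["tetrad", "chrom"], sort=False):
        p = np.sort(grp["pos"].to_numpy(dtype=float))
        if p.size >= 2:
            gaps.append(np.diff(p))
    return np.concatenate(gaps) if gaps else np.empty(0)


def interference_test(
    co_positions: pd.DataFrame,
    layout: GenomeLayout,
    n_sims: int = 1000,
    seed: int | None = None,
) -> InterferenceResult:
    """Compare observed inter-crossover distances with a no-interference null.

    ``co_positions`` needs columns tetrad, chrom, pos (crossover midpoints).
    The null preserves each tetrad's crossover count and places crossovers
    uniformly at random over the genome.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    obs_gaps = _pooled_gaps(co_positions)
    if obs_gaps.size == 0:
        raise ValueError("no same-chromosome adjacent crossover pairs; test undefined")
    rng = np.random.default_rng(seed)
    chroms = layout.chromosomes
    lengths = chroms["length"].to_numpy(dtype=float)
    p = lengths / lengths.sum()
    counts = co_positions.groupby("tetrad", sort=False).size().to_numpy()
    n_total = int(counts.sum())
    tet_ids = np.repeat(np.arange(counts.size), counts)

    sim_medians = np.empty(n_sims)
    sim_gap_pool: list[np.ndarray] = []
    for s in range(n_sims):
        ci = rng.choice(lengths.size, size=n_total, p=p)
        x = rng.random(n_total) * lengths[ci]
        order = np.lexsort((x, ci, tet_ids))
        ci_s, tid_s, x_s = ci[order], tet_ids[order], x[order]
        same = (ci_s[1:] == ci_s[:-1]) & (tid_s[1:] == tid_s[:-1])
        gaps = (x_s[1:] - x_s[:-1])[same]
        sim_medians[s] = np.median(gaps) if gaps.size else np.nan
        sim_gap_pool.append(gaps)
    sims = np.concatenate(sim_gap_pool)
    stat = sps.mannwhitneyu(obs_gaps, sims, alternative="greater")
    return InterferenceResult(
        observed_median=float(np.median(obs_gaps)),
        expected_median=float(np.nanmedian(sim_medians)),
        p_value=float(stat.pvalue),
        n_sims=n_sims,
        n_gaps=int(obs_gaps.size),
        sim_medians=sim_medians,
    )


def co_midpoints(events: Sequence[RecombEvent]) -> pd.DataFrame:
    """Crossover midpoints for gap statistics: the transition-interval
    midpoint for conversionless crossovers, the conversion-tract midpoint
    otherwise."""
    rows = [
        (e.tetrad_id, e.chrom, e.position) for e in events if e.cls in CO_CLASSES
    ]
    return pd.DataFrame(rows, columns=["tetrad", "chrom", "pos"])


# ---------------------------------------------------------------------------
# categorical tests on printed-style tallies
# ---------------------------------------------------------------------------

ABERRANT_PATTERNS = ("3:1", "1:3", "4:0", "0:4")


def aberrant_segregation_proportion(counts: Mapping[str, int]) -> tuple[float, int, int]:
    """(proportion, n_aberrant, n_total) from a segregation-pattern tally
    (keys among 2:2, 3:1, 1:3, 4:0, 0:4)."""
    if not counts or sum(counts.values()) == 0:
        raise ValueError("empty segregation tally")
    n_ab = sum(counts.get(k, 0) for k in ABERRANT_PATTERNS)
    n_tot = n_ab + counts.get("2:2", 0)
    return n_ab / n_tot, n_ab, n_tot


def viability_proportion(viable: int, total: int) -> float:
    if total <= 0 or viable < 0 or viable > total:
        raise ValueError("invalid viability counts")
    return viable / total


def fisher_test(a_succ: int, a_tot: int, b_succ: int, b_tot: int) -> float:
    """Two-tailed Fisher exact test comparing two proportions."""
    table = [[a_succ, a_tot - a_succ], [b_succ, b_tot - b_succ]]
    return float(sps.fisher_exact(table)[1])


def chi2_test(a_succ: int, a_tot: int, b_succ: int, b_tot: int) -> float:
    """2x2 contingency chi-square (no continuity correction) on two proportions."""
    table = np.array([[a_succ, a_tot - a_succ], [b_succ, b_tot - b_succ]])
    return float(sps.chi2_contingency(table, correction=False)[1])


def segregation_summary(
    counts_by_condition: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Aberrant-segregation proportions per condition with pairwise Fisher
    exact p-values against every other condition."""
    rows = []
    stats_by = {
        lab: aberrant_segregation_proportion(c) for lab, c in counts_by_condition.items()
    }
    for lab, (prop, n_ab, n_tot) in stats_by.items():
        row = {"condition": lab, "n_aberrant": n_ab, "n_total": n_tot,
               "proportion": prop, "percent": round(100 * prop, 1)}
        for other, (_, ob, ot) in stats_by.items():
            if other != lab:
                row[f"p_vs_{other}"] = fisher_test(n_ab, n_tot, ob, ot)
        rows.append(row)
    return pd.DataFrame(rows)
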