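"""Synthetic data with planted ground truth.

Two generators emulate the study's two data types:

* :func:`simulate_tetrads` plants meiotic recombination events — reciprocal
  crossovers with conversion tracts, non-crossover conversion tracts
  (simple/complex), and terminal break-induced-replication tracts — onto the
  four chromatids of each tetrad and returns both the genotype tables and a
  :class:`PlantedTruth` event log.
* :func:`simulate_probe_arrays` turns a latent per-probe hotspot activity
  landscape into replicate ChIP-chip signal/control tables.

Model notes
-----------
Crossover counts per chromosome are Poisson with mean proportional to
chromosome length; positions use the gamma-spacings construction (n+1
Gamma(shape) gaps rescaled to the chromosome), which reduces exactly to
uniform order statistics at ``interference_shape = 1`` and spaces crossovers
more evenly for shape > 1. Every crossover carries a conversion tract
(lognormal length, default median 3 kb); a crossover whose tract covers no
marker is *observed* as a conversionless exchange, which is the premise of the
downstream detectable-fraction correction. Conversion tracts produce exact
3:1 marker segregation; crossovers never disturb 2:2 segregation.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .genotypes import CALL_LABELS, MISSING, P1, P2, TetradGenotypes


@dataclass
class PlantedTruth:
    """Ground truth written alongside simulated data.

    ``events`` has one row per planted recombination event with both the
    planted anatomy (``planted_class``) and the class the event presents on
    the marker map (``observable_class``; NaN when no marker falls in the
    tract). ``co_counts`` is the planted crossover count per tetrad.
    """

    landscape: np.ndarray | None = None
    hotspots: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    co_counts: np.ndarray | None = None

    def co_positions(self) -> pd.DataFrame:
        """Planted crossover exchange points (tetrad, chrom, pos)."""
        if self.events is None:
            raise ValueError("no planted events")
        co = self.events[self.events["co_associated"]]
        return co.rename(columns={"anchor": "pos"})[["tetrad", "chrom", "pos"]].reset_index(
            drop=True
        )

    def to_json(self, path) -> None:
        payload: dict = {}
        if self.landscape is not None:
            payload["landscape"] = [float(x) for x in self.landscape]
        if self.hotspots is not None:
            payload["hotspots"] = self.hotspots.to_dict(orient="records")
        if self.events is not None:
            ev = self.events.copy()
            ev["observable_class"] = ev["observable_class"].astype(object).where(
                ev["observable_class"].notna(), None
            )
            payload["events"] = ev.to_dict(orient="records")
        if self.co_counts is not None:
            payload["co_counts"] = [int(x) for x in self.co_counts]
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            landscape=np.asarray(payload["landscape"]) if "landscape" in payload else None,
            hotspots=pd.DataFrame(payload["hotspots"]) if "hotspots" in payload else None,
            events=pd.DataFrame(payload["events"]) if "events" in payload else None,
            co_counts=np.asarray(payload["co_counts"]) if "co_counts" in payload else None,
        )


_EVENT_COLUMNS = [
    "tetrad",
    "planted_class",
    "observable_class",
    "chrom",
    "anchor",
    "tract_start",
    "tract_end",
    "chromatids",
    "donor",
    "co_associated",
    "n_converted_markers",
]


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: float, sigma: float, minimum: float
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    draw = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.maximum(draw, minimum)


def _converted_runs(mask: np.ndarray) -> int:
    """Number of maximal True-runs in a boolean marker mask."""
    if mask.size == 0:
        return 0
    m = mask.astype(np.int8)
    return int(m[0] + np.sum((m[1:] == 1) & (m[:-1] == 0)))


def simulate_tetrads(
    layout: GenomeLayout,
    n_tetrads: int,
    co_per_tetrad: float = 107.0,
    interference_shape: float = 1.0,
    nco_per_tetrad: float = 67.0,
    tract_median_bp: float = 3000.0,
    tract_sigma: float = 0.45,
    complex_prob: float = 0.05,
    bir_rate: float = 0.5,
    seed: int | None = None,
    *,
    tract_min_bp: float = 0.0,
    bir_min_bp: float = 5000.0,
    bir_extra_median_bp: float = 10_000.0,
    obligate_co: bool = True,
    min_event_sep: float = 0.0,
    ensure_visible: bool = True,
) -> tuple[list[TetradGenotypes], PlantedTruth]:
    """Simulate tetrads with planted crossovers, conversions, and BIR events.

    Defaults reflect the 30 degC condition of the study design: ~107
    crossovers and ~67 (detection-corrected) non-crossover conversions per
    tetrad, conversion tract median ~3 kb, a few percent complex events, and
    roughly one BIR event every other tetrad.

    Parameters
    ----------
    interference_shape : gamma shape of the inter-crossover gap distribution;
        1 gives no interference (uniform placement), larger values space
        crossovers more evenly.
    min_event_sep : if > 0, planted events closer than this (bp, anchor to
        anchor) are thinned greedily so events do not interact; used by
        recovery tests.
    ensure_visible : draw the two crossover chromatids uniformly among
        homolog pairs whose current origins differ at the exchange point, so
        every planted crossover is visible as an origin transition.
    obligate_co : force at least one crossover per chromosome per tetrad.

    Returns
    -------
    (tetrads, truth) where ``truth.events`` logs every planted event and
    ``truth.co_counts`` the planted crossover count per tetrad.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    if co_per_tetrad < 0 or nco_per_tetrad < 0 or bir_rate < 0:
        raise ValueError("event rates must be non-negative")
    if not (0.0 <= complex_prob <= 1.0):
        raise ValueError("complex_prob must be in [0, 1]")
    if tract_median_bp <= 0 or tract_sigma < 0:
        raise ValueError("conversion tract distribution must have positive support")
    if interference_shape <= 0:
        raise ValueError("interference_shape must be positive")

    rng = np.random.default_rng(seed)
    chroms = layout.chromosomes
    lengths = chroms["length"].to_numpy(dtype=float)
    total_len = lengths.sum()
    chrom_names = list(chroms["name"])
    marker_pos = {c: layout.marker_positions(c) for c in chrom_names}
    # layout.markers row-slice offsets per chromosome, in table order
    offsets, off = {}, 0
    for c in chrom_names:
        offsets[c] = off
        off += marker_pos[c].size

    tetrads: list[TetradGenotypes] = []
    event_rows: list[tuple] = []
    co_counts = np.zeros(n_tetrads, dtype=int)

    for t in range(n_tetrads):
        tid = f"tetrad{t + 1}"
        calls = np.empty((layout.n_markers, 4), dtype=np.int8)
        for ci, cname in enumerate(chrom_names):
            L = lengths[ci]
            pos = marker_pos[cname]
            n = pos.size
            orig = np.zeros((n, 4), dtype=np.int8)
            orig[:, 2:] = P2

            # ---- draw events --------------------------------------------------
            n_co = int(rng.poisson(co_per_tetrad * L / total_len))
            if obligate_co:
                n_co = max(n_co, 1)
            gaps = rng.gamma(interference_shape, 1.0, size=n_co + 1)
            co_x = L * np.cumsum(gaps[:-1]) / gaps.sum()
            n_nco = int(rng.poisson(nco_per_tetrad * L / total_len))
            nco_x = np.sort(rng.uniform(0.0, L, size=n_nco))
            # BIR: Poisson per chromosome, rate proportional to length
            n_bir = int(rng.poisson(bir_rate * L / total_len))

            # Draw tract lengths with the candidates so interior events whose
            # tract would swallow the terminal marker can be dropped up front:
            # a tract running through the last marker is indistinguishable
            # from a terminal (BIR-like) event, which is planted separately.
            cand = []
            for kind, xs in (("co", co_x), ("nco", nco_x)):
                for x in xs:
                    tract_len = float(
                        _lognormal_lengths(rng, 1, tract_median_bp, tract_sigma, tract_min_bp)[0]
                    )
                    complex_ev = bool(rng.random() < complex_prob)
                    span = 7400.0 if complex_ev else tract_len
                    if pos.size and (x <= pos[0] or x + span >= pos[-1]):
                        continue
                    cand.append((kind, float(x), tract_len, complex_ev))
            for _ in range(n_bir):
                blen = bir_min_bp + float(
                    _lognormal_lengths(rng, 1, bir_extra_median_bp, tract_sigma, 0.0)[0]
                )
                blen = min(blen, L - 1.0)
                right_end = bool(rng.integers(0, 2))
                anchor = L - blen if right_end else blen
                cand.append(("bir_right" if right_end else "bir_left", float(anchor), blen, False))
            cand.sort(key=lambda e: e[1])
            if min_event_sep > 0:
                kept, last = [], -np.inf
                for ev_tuple in cand:
                    kind, x = ev_tuple[0], ev_tuple[1]
                    if x - last >= min_event_sep and (
                        not kind.startswith("bir") or x >= min_event_sep
                    ):
                        kept.append(ev_tuple)
                        last = x
                cand = kept

            # ---- apply events left to right -----------------------------------
            n_co_applied = 0
            for kind, x, tract_len, complex_ev in cand:
                ix = int(np.searchsorted(pos, x, side="left"))
                ref = min(ix, n - 1) if n else 0
                if n == 0:
                    continue
                if kind == "co":
                    n_co_applied += 1
                    pairs = [(a, b) for a in (0, 1) for b in (2, 3)]
                    if ensure_visible:
                        vis = [p for p in pairs if orig[ref, p[0]] != orig[ref, p[1]]]
                        pairs = vis or pairs
                    a, b = pairs[int(rng.integers(0, len(pairs)))]
                    tchrom = a if rng.integers(0, 2) == 0 else b
                    donor_val = int(orig[ref, tchrom])  # pre-exchange origin
                    orig[ix:, [a, b]] = orig[ix:, [b, a]]
                    segs = _plant_tract(
                        rng,
                        orig,
                        pos,
                        tchrom,
                        x,
                        tract_len,
                        donor_val,
                        complex_ev,
                        terminal_end=None,
                        chrom_len=L,
                    )
                    n_markers_conv = int(sum(seg_m for _, _, seg_m in segs))
                    runs = _runs_from_segments(pos, segs, x)
                    planted = 5 if complex_ev else 3
                    if ix <= 0 or ix >= n:
                        # exchange point outside the marker map: no transition
                        obs = float("nan")
                    else:
                        obs = float(5 if runs >= 2 else (3 if runs == 1 else 2))
                    tr_lo = min(s for s, _, _ in segs)
                    tr_hi = max(e for _, e, _ in segs)
                    event_rows.append(
                        (
                            tid,
                            planted,
                            float(obs),
                            cname,
                            float(x),
                            float(tr_lo),
                            float(tr_hi),
                            f"{min(a, b)},{max(a, b)}",
                            CALL_LABELS[donor_val],
                            True,
                            n_markers_conv,
                        )
                    )
                elif kind == "nco":
                    tchrom = int(rng.integers(0, 4))
                    donor_val = 1 - int(orig[ref, tchrom])
                    segs = _plant_tract(
                        rng,
                        orig,
                        pos,
                        tchrom,
                        x,
                        tract_len,
                        donor_val,
                        complex_ev,
                        terminal_end=None,
                        chrom_len=L,
                    )
                    n_markers_conv = int(sum(seg_m for _, _, seg_m in segs))
                    runs = _runs_from_segments(pos, segs, x)
                    planted = 4 if complex_ev else 1
                    obs = float("nan") if runs == 0 else (4.0 if runs >= 2 else 1.0)
                    tr_lo = min(s for s, _, _ in segs)
                    tr_hi = max(e for _, e, _ in segs)
                    event_rows.append(
                        (
                            tid,
                            planted,
                            obs,
                            cname,
                            float(x),
                            float(tr_lo),
                            float(tr_hi),
                            str(tchrom),
                            CALL_LABELS[donor_val],
                            False,
                            n_markers_conv,
                        )
                    )
                else:  # BIR: terminal nonreciprocal tract
                    tchrom = int(rng.integers(0, 4))
                    if kind == "bir_right":
                        sel = pos > x
                        lo, hi = x, L
                    else:
                        sel = pos <= x
                        lo, hi = 1.0, x
                    if sel.any():
                        first = int(np.flatnonzero(sel)[0])
                        donor_val = 1 - int(orig[first, tchrom])
                        orig[sel, tchrom] = donor_val
                    else:
                        donor_val = 1 - int(orig[ref, tchrom])
                    m = int(sel.sum())
                    event_rows.append(
                        (
                            tid,
                            6,
                            6.0 if m else float("nan"),
                            cname,
                            float(x),
                            float(lo),
                            float(hi),
                            str(tchrom),
                            CALL_LABELS[donor_val],
                            False,
                            m,
                        )
                    )
            co_counts[t] += n_co_applied
            calls[offsets[cname] : offsets[cname] + n, :] = orig
        tetrads.append(
            TetradGenotypes(tid, layout.markers[["marker_id", "chrom", "pos"]], calls)
        )

    events = pd.DataFrame(event_rows, columns=_EVENT_COLUMNS)
    truth = PlantedTruth(events=events, co_counts=co_counts)
    return tetrads, truth


def _plant_tract(
    rng: np.random.Generator,
    orig: np.ndarray,
    pos: np.ndarray,
    chromatid: int,
    x: float,
    tract_len: float,
    donor_val: int,
    complex_ev: bool,
    terminal_end,
    chrom_len: float,
) -> list[tuple[float, float, int]]:
    """Write a conversion tract (possibly 2-3 alternating sub-tracts) onto one
    chromatid, starting just right of ``x``. Returns converted segments as
    (start, end, n_markers)."""
    x = min(x, chrom_len - tract_len - 1.0)
    x = max(x, 0.0)
    if not complex_ev:
        segs = [(x, x + tract_len)]
    else:
        # 2-3 converted sub-tracts separated by unconverted gaps, total span
        # capped just under the 7.5-kb complex-merge rule so the classifier's
        # merge boundary is exercised.
        n_sub = int(rng.integers(2, 4))
        pieces = _lognormal_lengths(rng, 2 * n_sub - 1, max(tract_len, 1000.0) / 2, 0.4, 200.0)
        cap = 7200.0
        if pieces.sum() > cap:
            pieces = pieces * (cap / pieces.sum())
        edges = x + np.concatenate([[0.0], np.cumsum(pieces)])
        edges = np.minimum(edges, chrom_len - 1.0)
        segs = [(edges[2 * i], edges[2 * i + 1]) for i in range(n_sub)]
    out = []
    for s, e in segs:
        sel = (pos > s) & (pos <= e)
        if sel.any():
            orig[sel, chromatid] = donor_val
        out.append((s, e, int(sel.sum())))
    return out


def _runs_from_segments(pos: np.ndarray, segs, x: float) -> int:
    """Observed converted-marker runs: sub-tracts whose markers are separated
    by at least one unconverted marker merge into one run."""
    lo = min(s for s, _, _ in segs)
    hi = max(e for _, e, _ in segs)
    span = (pos > lo) & (pos <= hi)
    if not span.any():
        return 0
    p = pos[span]
    conv = np.zeros(p.size, dtype=bool)
    for s, e, _ in segs:
        conv |= (p > s) & (p <= e)
    return _converted_runs(conv)


def degrade_genotypes(
    tetrads: Sequence[TetradGenotypes],
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> list[TetradGenotypes]:
    """Flip and/or mask marker calls independently at the given rates.

    Inputs are not modified; missing calls are never flipped.
    """
    for r, name in ((miscall_rate, "miscall_rate"), (missing_rate, "missing_rate")):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for td in tetrads:
        calls = td.calls.copy()
        present = calls != MISSING
        if miscall_rate > 0:
            flip = present & (rng.random(calls.shape) < miscall_rate)
            calls[flip] = 1 - calls[flip]
        if missing_rate > 0:
            mask = rng.random(calls.shape) < missing_rate
            calls[mask] = MISSING
        out.append(TetradGenotypes(td.tetrad_id, td.markers, calls))
    return out


# ---------------------------------------------------------------------------
# probe-array side
# ---------------------------------------------------------------------------


def hotspot_landscape(
    layout: GenomeLayout,
    n_hotspots: int = 400,
    fold: float = 10.0,
    width_bp: float = 2000.0,
    baseline: float = 1.0,
    seed: int | None = None,
    *,
    telomere_suppression: float = 0.0,
    telomere_span_bp: float = 20_000.0,
    centromere_suppression: float = 0.0,
    centromere_span_bp: float = 10_000.0,
    min_sep_bp: float = 10_000.0,
    centers: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Latent per-probe activity: flat baseline, planted hotspots, optional
    telomere/centromere suppression.

    Returns (activity array aligned to ``layout.probes``, hotspot table with
    chrom/start/end/center columns). Pass ``centers`` to reuse hotspot
    locations across conditions.
    """
    rng = np.random.default_rng(seed)
    probes = layout.probes
    mid = ((probes["start"] + probes["end"]) / 2).to_numpy(dtype=float)
    chrom_arr = probes["chrom"].to_numpy()
    lengths = layout.chrom_lengths()
    cens = layout.centromeres()

    if centers is None:
        centers = draw_hotspot_centers(layout, n_hotspots, min_sep_bp=min_sep_bp, rng=rng)
    activity = np.full(len(probes), float(baseline))
    half = width_bp / 2.0
    for _, row in centers.iterrows():
        sel = (chrom_arr == row["chrom"]) & (np.abs(mid - row["center"]) <= half)
        activity[sel] *= fold
    if telomere_suppression > 0:
        for c, L in lengths.items():
            sel = (chrom_arr == c) & (
                (mid <= telomere_span_bp) | (mid >= L - telomere_span_bp)
            )
            activity[sel] *= 1.0 - telomere_suppression
    if centromere_suppression > 0:
        for c, cen in cens.items():
            sel = (chrom_arr == c) & (np.abs(mid - cen) <= centromere_span_bp)
            activity[sel] *= 1.0 - centromere_suppression
    hot = centers.copy()
    hot["start"] = hot["center"] - half
    hot["end"] = hot["center"] + half
    return activity, hot


def draw_hotspot_centers(
    layout: GenomeLayout,
    n: int,
    min_sep_bp: float = 10_000.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hotspot centers: chromosome chosen proportional to length, position
    uniform, greedy minimum separation."""
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = layout.chromosomes
    lengths = chroms["length"].to_numpy(dtype=float)
    p = lengths / lengths.sum()
    rows: list[tuple[str, float]] = []
    placed: dict[str, list[float]] = {c: [] for c in chroms["name"]}
    attempts = 0
    while len(rows) < n and attempts < 50 * n:
        attempts += 1
        ci = int(rng.choice(len(lengths), p=p))
        c = chroms["name"].iloc[ci]
        x = float(rng.uniform(min_sep_bp, lengths[ci] - min_sep_bp))
        if all(abs(x - y) >= min_sep_bp for y in placed[c]):
            placed[c].append(x)
            rows.append((c, x))
    if len(rows) < n:
        raise ValueError("could not place hotspots at the requested separation")
    return pd.DataFrame(rows, columns=["chrom", "center"])


def temperature_landscapes(
    layout: GenomeLayout,
    labels: Sequence[str] = ("14C", "30C", "37C"),
    n_hotspots: int = 400,
    shared_frac: float = 0.2,
    pair_frac: float = 0.15,
    fold: float = 10.0,
    width_bp: float = 2000.0,
    seed: int | None = None,
    suppression: dict[str, dict] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, pd.DataFrame]]:
    """Three hotspot landscapes sharing a controlled fraction of hotspots.

    Each condition gets ``n_hotspots`` hotspots: ``shared_frac`` common to all
    three, ``pair_frac`` shared with each adjacent condition, the rest unique.
    ``suppression`` maps label -> extra keyword args of
    :func:`hotspot_landscape` (telomere/centromere suppression).
    """
    if len(labels) != 3:
        raise ValueError("exactly three condition labels required")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_frac * n_hotspots))
    n_pair = int(round(pair_frac * n_hotspots))
    n_unique = n_hotspots - n_shared - 2 * n_pair
    if n_unique < 0:
        raise ValueError("shared_frac + 2*pair_frac exceeds 1")
    total = n_shared + 3 * n_pair + 3 * n_unique
    pool = draw_hotspot_centers(layout, total, rng=rng)
    idx = 0

    def take(k):
        nonlocal idx
        part = pool.iloc[idx : idx + k]
        idx += k
        return part

    shared = take(n_shared)
    pairs = {frozenset(pr): take(n_pair) for pr in
             [(labels[0], labels[1]), (labels[1], labels[2]), (labels[0], labels[2])]}
    uniques = {lab: take(n_unique) for lab in labels}

    activities, hotspots = {}, {}
    for lab in labels:
        centers = pd.concat(
            [shared]
            + [df for key, df in pairs.items() if lab in key]
            + [uniques[lab]],
            ignore_index=True,
        )
        extra = (suppression or {}).get(lab, {})
        act, hot = hotspot_landscape(
            layout, fold=fold, width_bp=width_bp, centers=centers, **extra
        )
        activities[lab] = act
        hotspots[lab] = hot
    return activities, hotspots


def simulate_probe_arrays(
    layout: GenomeLayout,
    landscape: np.ndarray,
    n_replicates: int = 4,
    noise_sd: float = 0.25,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate ChIP signal/control intensities from a latent activity landscape.

    Signal is the latent activity with lognormal replicate noise
    (``2**Normal(0, noise_sd)``); control is pure noise around 1. The default
    four replicates mirror the study design of two sporulations with two
    immunoprecipitations each. Columns ``sig1..sigK`` / ``ctl1..ctlK`` are
    appended to the probe table; feed the result to
    :func:`meiorec.hotspots.normalize_signals`.
    """
    landscape = np.asarray(landscape, dtype=float)
    if landscape.shape != (layout.n_probes,):
        raise ValueError(
            f"landscape length {landscape.size} != probe count {layout.n_probes}"
        )
    if np.any(landscape <= 0):
        raise ValueError("latent activities must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    df = layout.probes.copy()
    for k in range(1, n_replicates + 1):
        df[f"sig{k}"] = landscape * 2.0 ** rng.normal(0.0, noise_sd, landscape.size)
        df[f"ctl{k}"] = 2.0 ** rng.normal(0.0, noise_sd, landscape.size)
    return df
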