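"""Detection and classification of recombination events in four-spore tetrads.

Parental-origin transitions on each chromatid are clustered along the
chromosome (successive transition midpoints within ``complex_merge_bp`` of
each other belong to one candidate event) and each cluster is resolved into
the six event classes:

1. simple gene conversion, no crossover (one chromatid, two transitions,
   3:1 interior, flanks unchanged);
2. crossover without detectable conversion (two chromatids, single
   transitions in the same marker interval, flanks reciprocally exchanged);
3. crossover with a simple conversion tract (two chromatids, single
   transitions at different boundaries, 3:1 interior);
4. complex conversion, no crossover (>2 transitions on the converted
   chromatid);
5. complex conversion with crossover;
6. break-induced replication (terminal nonreciprocal tract longer than
   ``bir_min_bp``).

Chromatids in a cluster that show no flanking exchange are split out as
their own conversion events, so a crossover and an independent nearby
conversion on a third chromatid are reported separately. Double conversions
(4:0-type, both chromatids of one parent converted at one locus) and
irresolvable clusters are emitted as unclassified records, never silently
dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import CALL_LABELS, MISSING, TetradGenotypes

DEFAULT_COMPLEX_MERGE_BP = 7500.0
DEFAULT_BIR_MIN_BP = 5000.0

UNCLASSIFIED = 0


@dataclass
class Transition:
    """A parental-origin switch between two adjacent non-missing markers."""

    spore: int
    left_index: int
    right_index: int
    left_pos: float
    right_pos: float

    @property
    def mid(self) -> float:
        return (self.left_pos + self.right_pos) / 2.0


@dataclass
class RecombEvent:
    tetrad_id: str
    chrom: str
    cls: int  # 1..6, or 0 = unclassified
    chromatids: tuple[int, ...]
    donor: str | None  # parent whose sequence is duplicated (P1/P2)
    co_associated: bool
    position: float  # representative midpoint for sorting/gap statistics
    tract_start: float | None = None  # marker-span tract bounds
    tract_end: float | None = None
    ext_start: float | None = None  # midpoint-extended tract bounds
    ext_end: float | None = None
    interval_left: float | None = None  # class-2 exchange interval
    interval_right: float | None = None
    n_transitions: int = 0
    segments: int = 0
    note: str = ""

    @property
    def tract_length(self) -> float | None:
        """Midpoint-extended tract length, used for tract statistics."""
        if self.ext_start is None or self.ext_end is None:
            return None
        return self.ext_end - self.ext_start


def smooth_ratios(values, window_markers: int = 9) -> np.ndarray:
    """Centered moving mean over non-missing values; window in markers.

    Edges use truncated windows; a window longer than the series broadcasts
    the global mean. Mirrors the nine-SNP moving-window display used to
    visualize spore hybridization ratios.
    """
    if window_markers < 1 or window_markers % 2 == 0:
        raise ValueError("window_markers must be an odd positive count")
    s = pd.Series(np.asarray(values, dtype=float))
    if window_markers > len(s):
        return np.full(len(s), s.mean())
    return s.rolling(window_markers, center=True, min_periods=1).mean().to_numpy()


def find_transitions(positions, calls) -> list[Transition]:
    """Origin transitions of one spore along one chromosome.

    Markers with missing calls are skipped, so a transition may span them;
    its midpoint is the mean of the flanking non-missing marker positions.
    """
    positions = np.asarray(positions, dtype=float)
    calls = np.asarray(calls)
    idx = np.flatnonzero(calls != MISSING)
    out: list[Transition] = []
    if idx.size < 2:
        return out
    vals = calls[idx]
    for j in np.flatnonzero(vals[1:] != vals[:-1]):
        li, ri = int(idx[j]), int(idx[j + 1])
        out.append(Transition(-1, li, ri, float(positions[li]), float(positions[ri])))
    return out


def segregation_pattern(tetrad: TetradGenotypes, marker_id: str) -> str:
    """Segregation label (2:2, 3:1, 1:3, 4:0, 0:4, incomplete) at one marker."""
    hits = np.flatnonzero((tetrad.markers["marker_id"] == marker_id).to_numpy())
    if hits.size == 0:
        raise KeyError(f"unknown marker {marker_id}")
    row = tetrad.calls[int(hits[0])]
    if (row == MISSING).any():
        return "incomplete"
    n1 = int((row == 0).sum())
    return f"{n1}:{4 - n1}"


def assemble_events(
    tetrad: TetradGenotypes,
    complex_merge_bp: float = DEFAULT_COMPLEX_MERGE_BP,
    bir_min_bp: float = DEFAULT_BIR_MIN_BP,
    chrom_lengths: dict[str, float] | None = None,
) -> list[RecombEvent]:
    """Group origin transitions into clusters and classify each into the six
    recombination-event classes.

    ``chrom_lengths`` lets terminal (BIR) tract lengths extend to the true
    chromosome end; without it the last marker position is used.
    """
    events: list[RecombEvent] = []
    markers = tetrad.markers
    for chrom, grp in markers.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        calls = tetrad.calls[rows, :]
        chrom_len = (chrom_lengths or {}).get(chrom)
        per_spore: dict[int, list[Transition]] = {}
        all_trans: list[Transition] = []
        for s in range(4):
            ts = find_transitions(pos, calls[:, s])
            for t in ts:
                t.spore = s
            per_spore[s] = ts
            all_trans.extend(ts)
        if not all_trans:
            continue
        all_trans.sort(key=lambda t: t.mid)
        # cluster by successive-midpoint gaps
        clusters: list[list[Transition]] = [[all_trans[0]]]
        for t in all_trans[1:]:
            if t.mid - clusters[-1][-1].mid <= complex_merge_bp:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        clusters = _rescue_long_tracts(clusters, pos, calls, complex_merge_bp)
        for cluster in clusters:
            events.extend(
                _classify_cluster(
                    tetrad.tetrad_id,
                    chrom,
                    pos,
                    calls,
                    cluster,
                    per_spore,
                    bir_min_bp,
                    chrom_len,
                )
            )
    return events


def _rescue_long_tracts(clusters, pos, calls, complex_merge_bp) -> list:
    """Re-join adjacent clusters split by a conversion tract longer than the
    merge radius.

    A tract longer than ``complex_merge_bp`` puts its two boundary transitions
    in different clusters, each looking like an unpartnered exchange. Two
    adjacent single-chromatid clusters are re-joined when the markers between
    them are (almost) all 3:1 — the signature of one long tract — which
    distinguishes a long conversion from two independent nearby crossovers
    (whose interior segregates 2:2).
    """
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        out = [clusters[0]]
        for nxt in clusters[1:]:
            cur = out[-1]
            if _joinable(cur, nxt, pos, calls, complex_merge_bp):
                out[-1] = cur + nxt
                merged = True
            else:
                out.append(nxt)
        clusters = out
    return clusters


def _odd_spores(cluster):
    counts: dict[int, list] = {}
    for t in cluster:
        counts.setdefault(t.spore, []).append(t)
    return {s: ts for s, ts in counts.items() if len(ts) % 2 == 1}


def _joinable(c1, c2, pos, calls, complex_merge_bp) -> bool:
    if c2[0].mid - c1[-1].mid > 5 * complex_merge_bp:
        return False
    # each side must have exactly one unpartnered exchange (odd transition
    # count); chromatids with even counts are self-contained conversions and
    # do not block the join
    odd1, odd2 = _odd_spores(c1), _odd_spores(c2)
    if len(odd1) != 1 or len(odd2) != 1:
        return False
    (a, ts_a), = odd1.items()
    (b, ts_b), = odd2.items()
    la = int(calls[ts_a[0].left_index, a])
    lb = int(calls[ts_b[0].left_index, b])
    if a == b:
        # one long simple tract: interior opposite the shared outer flanks
        ra = int(calls[ts_b[-1].right_index, b])
        if la == lb or la != ra:
            return False
    else:
        if la == lb:  # reciprocal exchange requires opposite left flanks
            return False
    lo_i, hi_i = ts_a[-1].right_index, ts_b[0].left_index
    if hi_i < lo_i:
        return False
    interior = _aberrant_indices(pos, calls, lo_i, hi_i)
    n_int = hi_i - lo_i + 1
    return n_int >= 1 and interior.size >= 0.8 * n_int


def _aberrant_indices(pos, calls, lo_i, hi_i) -> np.ndarray:
    """Marker indices in [lo_i, hi_i] whose four-spore pattern is 3:1/1:3."""
    block = calls[lo_i : hi_i + 1]
    n1 = (block == 0).sum(axis=1)
    n2 = (block == 1).sum(axis=1)
    ab = ((n1 == 3) & (n2 == 1)) | ((n1 == 1) & (n2 == 3))
    return np.flatnonzero(ab) + lo_i


def _runs(indices: np.ndarray) -> int:
    if indices.size == 0:
        return 0
    return int(1 + np.sum(np.diff(indices) > 1))


def _classify_cluster(
    tid, chrom, pos, calls, cluster, per_spore, bir_min_bp, chrom_len
) -> list[RecombEvent]:
    by_spore: dict[int, list[Transition]] = {}
    for t in cluster:
        by_spore.setdefault(t.spore, []).append(t)
    info = {}
    for s, ts in by_spore.items():
        left = int(calls[ts[0].left_index, s])
        right = int(calls[ts[-1].right_index, s])
        info[s] = (ts, left, right, left != right)
    exchanged = [s for s in info if info[s][3]]
    converted = [s for s in info if not info[s][3]]
    out: list[RecombEvent] = []

    # --- conversion-only chromatids (no flanking exchange) -------------------
    conv_events: list[tuple[RecombEvent, set[int]]] = []
    reciprocal_cands: list[int] = []  # non-exchanged chromatids whose interior
    # segregates 2:2 — the signature of paired reciprocal exchanges (e.g. a
    # two-strand double crossover), not of a conversion tract
    for s in converted:
        ts, left, right, _ = info[s]
        lo_i, hi_i = ts[0].left_index, ts[-1].right_index
        seg = calls[lo_i : hi_i + 1, s]
        nonmiss = np.flatnonzero(seg != MISSING)
        conv_rel = nonmiss[seg[nonmiss] != left]
        conv_idx = conv_rel + lo_i
        if conv_idx.size == 0:
            out.append(
                RecombEvent(
                    tid, chrom, UNCLASSIFIED, (s,), None, False,
                    position=float(np.mean([t.mid for t in ts])),
                    n_transitions=len(ts), note="no converted markers",
                )
            )
            continue
        block = calls[conv_idx]
        n1 = (block == 0).sum(axis=1)
        n2 = (block == 1).sum(axis=1)
        frac_2to2 = float(((n1 == 2) & (n2 == 2)).mean())
        if frac_2to2 > 0.5:
            # interior still segregates 2:2: paired reciprocal exchange,
            # not a conversion tract (4:0 doubles stay on the conversion path)
            reciprocal_cands.append(s)
            continue
        runs = _runs(conv_idx)
        ev = RecombEvent(
            tid,
            chrom,
            1 if runs == 1 else 4,
            (s,),
            CALL_LABELS[1 - left],
            False,
            position=(ts[0].mid + ts[-1].mid) / 2.0,
            tract_start=float(pos[conv_idx[0]]),
            tract_end=float(pos[conv_idx[-1]]),
            ext_start=ts[0].mid,
            ext_end=ts[-1].mid,
            n_transitions=len(ts),
            segments=runs,
        )
        conv_events.append((ev, set(conv_idx.tolist())))
    # 4:0-type double conversions: overlapping converted markers on two
    # non-exchanged chromatids are emitted as one unclassified-multi record.
    used = [False] * len(conv_events)
    for i in range(len(conv_events)):
        if used[i]:
            continue
        group = [i]
        for j in range(i + 1, len(conv_events)):
            if not used[j] and conv_events[i][1] & conv_events[j][1]:
                group.append(j)
                used[j] = True
        if len(group) == 1:
            out.append(conv_events[i][0])
        else:
            evs = [conv_events[g][0] for g in group]
            out.append(
                RecombEvent(
                    tid, chrom, UNCLASSIFIED,
                    tuple(sorted(c for e in evs for c in e.chromatids)),
                    None, False,
                    position=float(np.mean([e.position for e in evs])),
                    n_transitions=sum(e.n_transitions for e in evs),
                    note="unclassified-multi: double conversion",
                )
            )

    # --- reciprocal rescues for merged crossovers ----------------------------
    # Two chromatids with matching even transition sets and a 2:2 interior are
    # paired reciprocal exchanges (a double crossover on one chromatid pair);
    # one such chromatid plus two same-direction exchanged chromatids is a
    # double crossover sharing that chromatid.
    exchanged_consumed = False
    if reciprocal_cands:
        rc = sorted(reciprocal_cands)
        resolved = False
        if len(rc) == 2 and not exchanged and info[rc[0]][1] != info[rc[1]][1]:
            # complementary flanks: a reciprocal swap, not a 4:0 double conversion
            ts_a, ts_b = info[rc[0]][0], info[rc[1]][0]
            if len(ts_a) == len(ts_b) and len(ts_a) % 2 == 0:
                # each consecutive transition pair delimits a phase-swapped
                # block; a genuine double exchange swaps a block of >=2
                # markers, whereas complementary miscalls at one marker do
                # not and are reported unclassified instead
                for i in range(0, len(ts_a), 2):
                    t1, t2 = ts_a[i], ts_a[i + 1]
                    blk = slice(t1.right_index, t2.left_index + 1)
                    av, bv = calls[blk, rc[0]], calls[blk, rc[1]]
                    complementary = bool(
                        ((av != bv) | (av == MISSING) | (bv == MISSING)).all()
                    )
                    n_block = t2.left_index - t1.right_index + 1
                    if n_block >= 2 and complementary:
                        out.append(_co_event(tid, chrom, pos, calls, rc[0], [t1], rc[1], [ts_b[i]]))
                        out.append(
                            _co_event(tid, chrom, pos, calls, rc[0], [t2], rc[1], [ts_b[i + 1]])
                        )
                    else:
                        out.append(
                            RecombEvent(
                                tid, chrom, UNCLASSIFIED, tuple(rc), None, False,
                                position=(t1.mid + t2.mid) / 2.0,
                                n_transitions=4,
                                note="single-marker phase swap",
                            )
                        )
                resolved = True
        elif (
            len(rc) == 1
            and len(exchanged) == 2
            and info[exchanged[0]][1] == info[exchanged[1]][1]
            and len(info[rc[0]][0]) == 2
        ):
            ex_sorted = sorted(exchanged, key=lambda s: info[s][0][0].mid)
            for t1, s2 in zip(info[rc[0]][0], ex_sorted):
                out.append(_co_event(tid, chrom, pos, calls, rc[0], [t1], s2, info[s2][0]))
            resolved = True
            exchanged_consumed = True
        if not resolved:
            out.append(
                _unclassified(
                    tid, chrom, info, rc, "reciprocal interior without exchanged partner"
                )
            )

    # --- exchanged chromatids ------------------------------------------------
    if exchanged_consumed:
        pass
    elif len(exchanged) == 2:
        a, b = exchanged
        if info[a][1] == info[b][1]:
            out.append(_unclassified(tid, chrom, info, exchanged, "non-reciprocal exchange"))
        else:
            out.append(_co_event(tid, chrom, pos, calls, a, info[a][0], b, info[b][0]))
    elif len(exchanged) == 1:
        s = exchanged[0]
        ts, left, right, _ = info[s]
        # terminal nonreciprocal tract (BIR) or an unpartnered exchange
        is_last = per_spore[s] and per_spore[s][-1] is ts[-1]
        is_first = per_spore[s] and per_spore[s][0] is ts[0]
        ev = None
        if is_last:
            start_i = ts[-1].right_index
            conv_idx = _aberrant_indices(pos, calls, start_i, len(pos) - 1)
            side_idx = np.flatnonzero(calls[start_i:, s] != MISSING) + start_i
            if side_idx.size and conv_idx.size >= max(1, side_idx.size // 2):
                end = float(chrom_len) if chrom_len else float(pos[-1])
                length = end - ts[-1].mid
                if length > bir_min_bp:
                    ev = RecombEvent(
                        tid, chrom, 6, (s,), CALL_LABELS[int(calls[side_idx[0], s])],
                        False, position=ts[-1].mid,
                        tract_start=float(pos[side_idx[0]]), tract_end=float(pos[side_idx[-1]]),
                        ext_start=ts[-1].mid, ext_end=end,
                        n_transitions=len(ts), segments=_runs(conv_idx),
                        note="terminal (right)",
                    )
        if ev is None and is_first:
            end_i = ts[0].left_index
            conv_idx = _aberrant_indices(pos, calls, 0, end_i)
            side_idx = np.flatnonzero(calls[: end_i + 1, s] != MISSING)
            if side_idx.size and conv_idx.size >= max(1, side_idx.size // 2):
                length = ts[0].mid - 1.0
                if length > bir_min_bp:
                    ev = RecombEvent(
                        tid, chrom, 6, (s,), CALL_LABELS[int(calls[side_idx[0], s])],
                        False, position=ts[0].mid,
                        tract_start=float(pos[side_idx[0]]), tract_end=float(pos[side_idx[-1]]),
                        ext_start=1.0, ext_end=ts[0].mid,
                        n_transitions=len(ts), segments=_runs(conv_idx),
                        note="terminal (left)",
                    )
        out.append(ev if ev is not None else _unclassified(tid, chrom, info, [s], "lone exchange"))
    elif len(exchanged) > 2:
        # Several crossovers merged into one cluster. An even, flank-balanced
        # set of exchanged chromatids is resolved into reciprocal pairs by
        # position; anything else is reported unclassified.
        up = [s for s in exchanged if info[s][1] == 0]
        down = [s for s in exchanged if info[s][1] == 1]
        if len(up) == len(down) and up:
            key = lambda s: float(np.mean([t.mid for t in info[s][0]]))
            up.sort(key=key)
            down.sort(key=key)
            for a, b in zip(up, down):
                out.append(_co_event(tid, chrom, pos, calls, a, info[a][0], b, info[b][0]))
        else:
            out.append(
                _unclassified(tid, chrom, info, exchanged, "unpaired exchanged chromatids")
            )
    return out


def _co_event(tid, chrom, pos, calls, a, ts_a, b, ts_b) -> RecombEvent:
    """Classify a reciprocal pair of exchanged chromatids (class 2, 3, or 5)."""
    lo_i = min(ts_a[0].left_index, ts_b[0].left_index)
    hi_i = max(ts_a[-1].right_index, ts_b[-1].right_index)
    conv_idx = _aberrant_indices(pos, calls, lo_i, hi_i)
    t_max = max(len(ts_a), len(ts_b))
    mids = [t.mid for t in ts_a + ts_b]
    n_trans = len(ts_a) + len(ts_b)
    cls = 5 if t_max > 1 else (3 if conv_idx.size else 2)
    if cls == 2:
        il = max(ts_a[0].left_pos, ts_b[0].left_pos)
        ir = min(ts_a[0].right_pos, ts_b[0].right_pos)
        return RecombEvent(
            tid, chrom, 2, (min(a, b), max(a, b)), None, True,
            position=(il + ir) / 2.0,
            interval_left=float(il), interval_right=float(ir),
            n_transitions=n_trans, segments=0,
        )
    donor = None
    if conv_idx.size:
        block = calls[conv_idx]
        n1 = (block == 0).sum(axis=1)
        n2 = (block == 1).sum(axis=1)
        # the duplicated parent holds 3 of 4 calls at aberrant markers
        donor = CALL_LABELS[0 if (n1 == 3).sum() >= (n2 == 3).sum() else 1]
    return RecombEvent(
        tid, chrom, cls, (min(a, b), max(a, b)), donor, True,
        position=(min(mids) + max(mids)) / 2.0,
        tract_start=float(pos[conv_idx[0]]) if conv_idx.size else None,
        tract_end=float(pos[conv_idx[-1]]) if conv_idx.size else None,
        ext_start=min(mids),
        ext_end=max(mids),
        n_transitions=n_trans,
        segments=_runs(conv_idx),
    )


def _unclassified(tid, chrom, info, spores, why) -> RecombEvent:
    mids = [t.mid for s in spores for t in info[s][0]]
    return RecombEvent(
        tid, chrom, UNCLASSIFIED, tuple(sorted(spores)), None, False,
        position=float(np.mean(mids)),
        n_transitions=sum(len(info[s][0]) for s in spores),
        note=why,
    )


def events_to_frame(events: list[RecombEvent]) -> pd.DataFrame:
    """Events as a flat table (one row per event), mirroring a per-tetrad
    event catalogue."""
    rows = []
    for e in events:
        rows.append(
            {
                "tetrad": e.tetrad_id,
                "chrom": e.chrom,
                "class": e.cls,
                "chromatids": ",".join(str(c) for c in e.chromatids),
                "donor": e.donor if e.donor is not None else "NA",
                "co_associated": e.co_associated,
                "position": e.position,
                "tract_start": e.tract_start,
                "tract_end": e.tract_end,
                "ext_start": e.ext_start,
                "ext_end": e.ext_end,
                "interval_left": e.interval_left,
                "interval_right": e.interval_right,
                "n_transitions": e.n_transitions,
                "segments": e.segments,
                "note": e.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tetrad", "chrom", "class", "chromatids", "donor", "co_associated",
            "position", "tract_start", "tract_end", "ext_start", "ext_end",
            "interval_left", "interval_right", "n_transitions", "segments", "note",
        ],
    )


def events_from_frame(df: pd.DataFrame) -> list[RecombEvent]:
    out = []
    for _, r in df.iterrows():
        out.append(
            RecombEvent(
                tetrad_id=r["tetrad"],
                chrom=r["chrom"],
                cls=int(r["class"]),
                chromatids=tuple(int(x) for x in str(r["chromatids"]).split(",") if x != ""),
                donor=None if pd.isna(r["donor"]) or r["donor"] == "NA" else r["donor"],
                co_associated=bool(r["co_associated"]),
                position=float(r["position"]),
                tract_start=None if pd.isna(r["tract_start"]) else float(r["tract_start"]),
                tract_end=None if pd.isna(r["tract_end"]) else float(r["tract_end"]),
                ext_start=None if pd.isna(r["ext_start"]) else float(r["ext_start"]),
                ext_end=None if pd.isna(r["ext_end"]) else float(r["ext_end"]),
                interval_left=None if pd.isna(r["interval_left"]) else float(r["interval_left"]),
                interval_right=None if pd.isna(r["interval_right"]) else float(r["interval_right"]),
                n_transitions=int(r["n_transitions"]),
                segments=int(r["segments"]),
                note="" if pd.isna(r["note"]) else str(r["note"]),
            )
        )
    return out
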