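import numpy as np
import pytest

from meiorec.events import (
    assemble_events,
    find_transitions,
    segregation_pattern,
    smooth_ratios,
)
from meiorec.simulate import simulate_tetrads
from tests.conftest import tetrad_from_strings


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def test_smoothing_constant_and_identity():
    x = np.full(20, 1.7)
    np.testing.assert_allclose(smooth_ratios(x, 9), x)
    y = np.random.default_rng(0).normal(size=15)
    np.testing.assert_allclose(smooth_ratios(y, 1), y)


def test_smoothing_matches_truncated_window_oracle():
    rng = np.random.default_rng(1)
    y = rng.normal(size=30)
    w = 9
    got = smooth_ratios(y, w)
    # direct oracle: mean over the centered window clipped at the edges
    half = w // 2
    expect = np.array(
        [y[max(0, i - half) : min(len(y), i + half + 1)].mean() for i in range(len(y))]
    )
    np.testing.assert_allclose(got, expect)


def test_smoothing_step_produces_ramp():
    y = np.array([0.0] * 20 + [1.0] * 20)
    sm = smooth_ratios(y, 9)
    assert sm[10] == 0.0 and sm[30] == 1.0
    ramp = sm[16:24]
    assert (np.diff(ramp) > 0).all()


def test_smoothing_window_larger_than_series_and_validation():
    y = np.array([1.0, 2.0, 3.0])
    np.testing.assert_allclose(smooth_ratios(y, 9), 2.0)
    with pytest.raises(ValueError):
        smooth_ratios(y, 4)
    with pytest.raises(ValueError):
        smooth_ratios(y, 0)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


def test_transition_detection_and_missing_skip():
    assert find_transitions([1000, 2000, 3000], [0, 0, 0]) == []
    tr = find_transitions([1000, 2000, 3000, 4000], [0, 0, 1, 1])
    assert len(tr) == 1 and tr[0].mid == 2500
    tr2 = find_transitions([1000, 2000, 3000], [0, -1, 1])
    assert len(tr2) == 1 and tr2[0].mid == 2000


def test_segregation_patterns():
    td = tetrad_from_strings(["1111", "1111", "2122", "2222"])
    assert segregation_pattern(td, "chrA_m1") == "2:2"
    assert segregation_pattern(td, "chrA_m2") == "3:1"
    td2 = tetrad_from_strings(["1", "1", "1", "1"])
    assert segregation_pattern(td2, "chrA_m1") == "4:0"
    td3 = tetrad_from_strings(["1", "N", "2", "2"])
    assert segregation_pattern(td3, "chrA_m1") == "incomplete"
    with pytest.raises(KeyError):
        segregation_pattern(td, "nope")


# ---------------------------------------------------------------------------
# event classification (the six classes)
# ---------------------------------------------------------------------------


def _single_event(td, **kw):
    events = assemble_events(td, **kw)
    assert len(events) == 1, [(e.cls, e.note) for e in events]
    return events[0]


def test_class1_simple_conversion_without_crossover():
    # spore B (index 1) carries an interior P2 tract on a P1 background
    td = tetrad_from_strings(
        ["1111111111", "1112221111", "2222222222", "2222222222"]
    )
    e = _single_event(td)
    assert e.cls == 1 and e.chromatids == (1,) and e.donor == "P2"
    assert not e.co_associated
    assert e.tract_start == 4000 and e.tract_end == 6000
    assert e.ext_start == 3500 and e.ext_end == 6500


def test_class2_crossover_without_conversion():
    td = tetrad_from_strings(
        ["1111111111", "1111122222", "2222211111", "2222222222"]
    )
    e = _single_event(td)
    assert e.cls == 2 and e.chromatids == (1, 2) and e.co_associated
    assert e.tract_start is None
    assert e.interval_left == 5000 and e.interval_right == 6000


def test_class3_crossover_with_simple_conversion():
    # transitions at different boundaries, 3:1 interior
    td = tetrad_from_strings(
        ["1111111111", "1112222222", "2222222111", "2222222222"]
    )
    e = _single_event(td)
    assert e.cls == 3 and e.chromatids == (1, 2) and e.co_associated
    assert e.donor == "P2"
    assert e.tract_start == 4000 and e.tract_end == 7000


def test_class4_complex_conversion_without_crossover():
    td = tetrad_from_strings(
        ["111111111111", "112211221111", "222222222222", "222222222222"]
    )
    e = _single_event(td)
    assert e.cls == 4 and e.chromatids == (1,) and e.segments == 2
    assert e.n_transitions == 4 and not e.co_associated


def test_class5_complex_conversion_with_crossover():
    td = tetrad_from_strings(
        ["111111111111", "112211222222", "222222221111", "222222222222"]
    )
    e = _single_event(td)
    assert e.cls == 5 and e.co_associated and set(e.chromatids) == {1, 2}
    assert e.segments >= 2


def test_class6_terminal_bir_tract():
    td = tetrad_from_strings(
        ["111111111111", "111122222222", "222222222222", "222222222222"]
    )
    e = _single_event(td, chrom_lengths={"chrA": 12_500})
    assert e.cls == 6 and e.chromatids == (1,) and e.donor == "P2"
    assert not e.co_associated and "terminal" in e.note


def test_short_terminal_tract_not_bir():
    td = tetrad_from_strings(["11111111", "11111122", "22222222", "22222222"])
    e = _single_event(td, chrom_lengths={"chrA": 8_500})
    assert e.cls == 0 and "lone" in e.note


def test_two_distant_conversions_stay_separate():
    s = ["1"] * 30
    s[4:6] = "22"
    s[20:22] = "22"
    td = tetrad_from_strings(["1" * 30, "".join(s), "2" * 30, "2" * 30])
    events = assemble_events(td)
    assert [e.cls for e in events] == [1, 1]


def test_nearby_conversions_merge_into_complex():
    s = ["1"] * 30
    s[4:6] = "22"
    s[8:10] = "22"
    td = tetrad_from_strings(["1" * 30, "".join(s), "2" * 30, "2" * 30])
    events = assemble_events(td)
    assert [e.cls for e in events] == [4]


def test_double_conversion_reported_unclassified():
    # both chromatids of one parent converted at the same markers: 4:0
    td = tetrad_from_strings(
        ["1112211111", "1112211111", "2222222222", "2222222222"]
    )
    events = assemble_events(td)
    assert len(events) == 1
    assert events[0].cls == 0 and "double conversion" in events[0].note


def test_transition_conservation_on_simulation(small_layout):
    tetrads, _ = simulate_tetrads(
        small_layout, 5, co_per_tetrad=25, nco_per_tetrad=15, bir_rate=0.3,
        min_event_sep=15_000, seed=30,
    )
    cl = small_layout.chrom_lengths()
    for td in tetrads:
        total = 0
        for chrom, grp in td.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            calls = td.calls[grp.index.to_numpy()]
            for s in range(4):
                total += len(find_transitions(pos, calls[:, s]))
        events = assemble_events(td, chrom_lengths=cl)
        assert sum(e.n_transitions for e in events) == total
        # clean well-separated data leaves nothing unclassified
        assert all(e.cls != 0 for e in events)


def test_detection_bias_short_tracts_lose_ncos_not_crossovers(small_layout):
    """Tracts shorter than the marker spacing escape NCO detection while
    crossover counts stay exact — the premise of the corrected NCO rate."""
    tetrads, truth = simulate_tetrads(
        small_layout, 6, co_per_tetrad=20, nco_per_tetrad=20, bir_rate=0,
        tract_median_bp=250.0, tract_sigma=0.3, min_event_sep=15_000, seed=31,
    )
    cl = small_layout.chrom_lengths()
    planted_nco = detected_nco = 0
    for td in tetrads:
        events = assemble_events(td, chrom_lengths=cl)
        co = sum(1 for e in events if e.cls in (2, 3, 5))
        te = truth.events[truth.events["tetrad"] == td.tetrad_id]
        assert co == int(te["co_associated"].sum())
        planted_nco += int((te["planted_class"].isin([1, 4])).sum())
        detected_nco += sum(1 for e in events if e.cls in (1, 4))
    assert detected_nco < 0.6 * planted_nco
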