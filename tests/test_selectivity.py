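import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_params, simulate_unit, unit_from_spike_lists

from songsel.selectivity import (
    RSStats,
    dprime,
    forward_reverse_bias,
    response_strength,
    rs_distribution_summary,
    selectivity_index,
    selectivity_result,
    song_comparison_panel,
    song_rs_table,
)
from songsel.session_io import Session
from songsel.stimuli import StimulusSpec, Syllable, make_stimulus_set


@pytest.fixture(scope="module")
def stims():
    return make_stimulus_set(0)


def _rs(vals, sid="A"):
    return RSStats(stimulus_id=sid, rs_per_trial=np.asarray(vals, dtype=float))


# --- response strength -----------------------------------------------------


def test_rs_arithmetic_from_printed_formula(stims):
    """ESR = (10, 12, 8), SSR = (2, 2, 2): rs = (8, 10, 6), mean 8, var 4.

    Built from spikes on a 1 s song: ESR_i spikes in the stimulus window,
    one spike in the 0.5 s pre window gives SSR_i = 2 spikes/s.
    """
    song = StimulusSpec(
        stimulus_id="S-1-FOR",
        category="SONG",
        duration_s=1.0,
        song_type="CON",
        direction="FOR",
        envelope=(Syllable(0.0, 1.0, 1.0, 500.0, 5000.0),),
    )
    reps = []
    for esr in (10, 12, 8):
        reps.append([0.1] + list(np.linspace(0.6, 1.4, esr)))
    u = unit_from_spike_lists([song], {"S-1-FOR": reps})
    stats = response_strength(u, "S-1-FOR")
    np.testing.assert_allclose(stats.rs_per_trial, [8.0, 10.0, 6.0])
    assert stats.mean_rs == pytest.approx(8.0)
    assert stats.var_rs == pytest.approx(4.0)
    assert stats.n == 3


def test_rs_zero_when_evoked_equals_baseline(stims):
    # 1 spike in pre (2/s) and 2 spikes during the 1 s WN stimulus (2/s)
    u = unit_from_spike_lists(stims, {"WN": [[0.1, 0.6, 1.2]] * 5})
    assert response_strength(u, "WN").mean_rs == pytest.approx(0.0)


def test_rs_unbiased_for_pure_spontaneous(stims):
    """Homogeneous Poisson units have mean RS ~ 0 within Monte-Carlo error."""
    rng = np.random.default_rng(0)
    means = []
    for _ in range(60):
        u = simulate_unit(
            make_params(spont=5.0, gain=0.0), stims, rng, stimulus_subset={"CON-1-FOR"}
        )
        means.append(response_strength(u, "CON-1-FOR").mean_rs)
    means = np.asarray(means)
    assert abs(means.mean()) < 2 * means.std(ddof=1) / np.sqrt(len(means))


def test_rs_requires_trials(stims):
    u = unit_from_spike_lists(stims, {"WN": [[0.1]]})
    with pytest.raises(ValueError):
        response_strength(u, "CON-1-FOR")


# --- selectivity index -----------------------------------------------------


def test_si_values_and_cutoffs():
    assert selectivity_index(_rs([3, 3, 3]), _rs([3, 3, 3], "B")) == pytest.approx(0.5)
    r = selectivity_result(_rs([2, 2]), _rs([1, 1], "B"))
    assert r.si == pytest.approx(2.0 / 3.0)
    assert r.si_selective  # 2/3 >= 0.66
    assert selectivity_index(_rs([-1, -1]), _rs([1, 1], "B")) is None


def test_si_cutoff_asymmetry_is_preserved():
    """The printed cut-offs are asymmetric: 2/3 >= 0.66 is selective but
    the mirrored 1/3 is NOT < 0.33."""
    hi = selectivity_result(_rs([2, 2]), _rs([1, 1], "B"))
    lo = selectivity_result(_rs([1, 1]), _rs([2, 2], "B"))
    assert hi.si_selective
    assert not lo.si_selective


@given(
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=0.01, max_value=100.0),
)
def test_si_complement_identity(a, b):
    """SI(A, B) + SI(B, A) == 1 whenever both are defined."""
    ra, rb = _rs([a, a]), _rs([b, b], "B")
    assert selectivity_index(ra, rb) + selectivity_index(rb, ra) == pytest.approx(
        1.0, abs=1e-12
    )


# --- d' --------------------------------------------------------------------


def test_dprime_hand_worked_example():
    """A = (3,1,2,2,2) [mean 2, var 0.5], B = (1,1,1,1,1): d' = 2/sqrt(0.5)."""
    d = dprime(_rs([3, 1, 2, 2, 2]), _rs([1, 1, 1, 1, 1], "B"))
    assert d == pytest.approx(2.0 / math.sqrt(0.5))
    assert selectivity_result(_rs([3, 1, 2, 2, 2]), _rs([1, 1, 1, 1, 1], "B")).dprime_selective


def test_dprime_identical_inputs_and_antisymmetry():
    a, b = _rs([4, 5, 6]), _rs([1, 2, 9], "B")
    assert dprime(a, a) == 0.0
    assert dprime(a, b) == -dprime(b, a)


def test_dprime_shift_and_scale_invariance():
    rng = np.random.default_rng(1)
    a = rng.normal(5, 2, 15)
    b = rng.normal(3, 1, 15)
    d0 = dprime(_rs(a), _rs(b, "B"))
    assert dprime(_rs(a + 7.5), _rs(b + 7.5, "B")) == pytest.approx(d0, rel=1e-12)
    assert dprime(_rs(3.0 * a), _rs(3.0 * b, "B")) == pytest.approx(d0, rel=1e-12)


def test_dprime_zero_variance_sentinel():
    assert dprime(_rs([2, 2]), _rs([2, 2], "B")) == 0.0
    r = selectivity_result(_rs([3, 3]), _rs([1, 1], "B"))
    assert math.isinf(r.dprime) and r.dprime > 0
    assert r.dprime_selective and r.dprime_degenerate
    with pytest.raises(ValueError):
        dprime(_rs([1.0]), _rs([2, 2], "B"))


# --- song panels -----------------------------------------------------------


def test_panel_has_six_comparisons_per_forward_song(stims):
    rng = np.random.default_rng(2)
    unit = simulate_unit(make_params(spont=2.0, gain=40.0), stims, rng)
    panel = song_comparison_panel(unit)
    assert len(panel) == 36  # 6 forward songs x (1 reverse + 5 forwards)
    per_song = {}
    for r in panel:
        per_song.setdefault(r.stimulus_a, []).append(r.stimulus_b)
    for fid, others in per_song.items():
        assert len(others) == 6
        assert fid[:-4] + "-REV" in others


def test_panel_skips_missing_stimuli(stims):
    rng = np.random.default_rng(3)
    keep = {s.stimulus_id for s in stims if s.category == "SONG"} - {"CON-1-REV"}
    unit = simulate_unit(make_params(), stims, rng, stimulus_subset=keep)
    panel = song_comparison_panel(unit)
    assert len(panel) == 35
    assert not any(r.stimulus_b == "CON-1-REV" for r in panel)


def test_panel_all_equal_responses_all_inside_zone(stims):
    spikes = [[0.6, 0.8, 1.1, 1.4]] * 15
    songs = {s.stimulus_id: list(spikes) for s in stims if s.category == "SONG"}
    # identical trains per repeat across songs of differing durations still
    # give d' = 0 within each FOR/REV pair (mirror has the same window)
    u = unit_from_spike_lists(stims, songs)
    panel = song_comparison_panel(u)
    for r in panel:
        if r.stimulus_a[:-4] == r.stimulus_b[:-4]:  # FOR vs its own REV
            assert r.dprime == 0.0
            assert not r.dprime_selective


def test_panel_flags_strongly_preferred_song():
    """A song driven 3x above the others dominates its comparison panel."""
    songs = []
    for stype in ("CON", "HET"):
        for i in (1, 2, 3):
            amp = 3.0 if (stype, i) == ("CON", 2) else 1.0
            fwd = StimulusSpec(
                stimulus_id=f"{stype}-{i}-FOR",
                category="SONG",
                duration_s=2.0,
                song_type=stype,
                direction="FOR",
                envelope=(Syllable(0.0, 2.0, amp, 500.0, 5000.0),),
            )
            songs.extend([fwd, fwd.mirrored(f"{stype}-{i}-REV", "REV")])
    rng = np.random.default_rng(4)
    unit = simulate_unit(make_params(spont=2.0, gain=30.0), songs, rng)
    panel = song_comparison_panel(unit)
    con2 = [r for r in panel if r.stimulus_a == "CON-2-FOR" and r.stimulus_b != "CON-2-REV"]
    assert sum(r.dprime > 2.0 for r in con2) >= 4


# --- forward/reverse bias --------------------------------------------------


def test_identity_line_distance(stims):
    spikes = {"CON-1-FOR": [[0.6] * 9] * 15, "CON-1-REV": [[0.6] * 9] * 15}
    u = unit_from_spike_lists(stims, spikes)
    df = forward_reverse_bias(u)
    assert df.loc[0, "signed_distance"] == pytest.approx(0.0)

    dur = next(s.duration_s for s in stims if s.stimulus_id == "CON-1-FOR")
    n_for, n_rev = round(4 * dur), round(2 * dur)
    spikes = {
        "CON-1-FOR": [list(np.linspace(0.6, 0.4 + dur, n_for))] * 15,
        "CON-1-REV": [list(np.linspace(0.6, 0.4 + dur, n_rev))] * 15,
    }
    df = forward_reverse_bias(unit_from_spike_lists(stims, spikes))
    expected = (n_for - n_rev) / dur / math.sqrt(2.0)
    assert df.loc[0, "signed_distance"] == pytest.approx(expected)
    assert df.loc[0, "signed_distance"] > 0  # FOR-preferring is positive


def test_reverse_preference_gives_negative_distances(stims):
    spikes = {"HET-2-FOR": [[0.7] * 3] * 15, "HET-2-REV": [[0.7] * 9] * 15}
    df = forward_reverse_bias(unit_from_spike_lists(stims, spikes))
    assert (df["signed_distance"] < 0).all()


# --- distribution summary --------------------------------------------------


def test_rs_summary_single_unit_single_song(stims):
    u = unit_from_spike_lists(stims, {"CON-1-FOR": [[0.6, 0.7]] * 15})
    table = song_rs_table(Session(stimuli=stims, units=[u]))
    assert len(table) == 1
    out = rs_distribution_summary(table)
    assert out.loc[("ZF-ZF", "CON"), "n"] == 1


def test_rs_summary_empty_rejected():
    import pandas as pd

    with pytest.raises(ValueError):
        rs_distribution_summary(pd.DataFrame())


# --- oracle equivalence ----------------------------------------------------


def test_formula_oracle_equivalence():
    """SI and d' match direct from-definition evaluations to 1e-12."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        a = rng.normal(rng.uniform(-2, 10), rng.uniform(0.1, 5), 15)
        b = rng.normal(rng.uniform(-2, 10), rng.uniform(0.1, 5), 15)
        ra, rb = _rs(a), _rs(b, "B")
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
        vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
        assert dprime(ra, rb) == pytest.approx(
            2 * (ma - mb) / math.sqrt(va + vb), rel=1e-12
        )
        si = selectivity_index(ra, rb)
        if ma > 0 and mb > 0:
            assert si == pytest.approx(ma / (ma + mb), rel=1e-12)
        else:
            assert si is None
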