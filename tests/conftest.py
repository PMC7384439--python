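import numpy as np
import pytest
from hypothesis import settings

from songsel import ScenarioConfig, UnitParams, simulate_session, simulate_trial
from songsel.session_io import Trial, UnitRecording
from songsel.stimuli import make_stimulus_set

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimulus_set():
    return make_stimulus_set(0)


@pytest.fixture(scope="session")
def small_session():
    """2 birds/group x 2 units, fixed seed; shared across read-only tests."""
    return simulate_session(
        ScenarioConfig(n_birds_per_group=2, units_per_bird=(2, 2), seed=11)
    )


def make_params(
    stimuli=None,
    spont=2.0,
    bf=2000.0,
    pattern="sustained",
    gain=50.0,
    con_gain=1.0,
    het_gain=1.0,
    inhibitory=(),
    unit_id="u0",
    bird_id="b0",
    group="ZF-ZF",
):
    return UnitParams(
        unit_id=unit_id,
        bird_id=bird_id,
        group=group,
        spont_rate_hz=spont,
        bf_hz=bf,
        tuning_bandwidth_oct=0.5,
        pattern=pattern,
        response_gain=gain,
        con_gain=con_gain,
        het_gain=het_gain,
        inhibitory_stimuli=frozenset(inhibitory),
    )


def simulate_unit(params, stimuli, rng, n_repeats=15, stimulus_subset=None):
    """Build a UnitRecording by simulating trials for (a subset of) stimuli."""
    use = [
        s
        for s in stimuli
        if stimulus_subset is None or s.stimulus_id in stimulus_subset
    ]
    trials = [
        Trial(s.stimulus_id, r, simulate_trial(params, s, rng), s.trial_duration_s)
        for s in use
        for r in range(n_repeats)
    ]
    n_base = rng.poisson(params.spont_rate_hz * 30.0)
    baseline = np.sort(rng.random(n_base) * 30.0)
    return UnitRecording(
        unit_id=params.unit_id,
        bird_id=params.bird_id,
        group=params.group,
        trials=trials,
        baseline=baseline,
        stimulus_table=list(stimuli),
    )


def unit_from_spike_lists(stimuli, per_trial_spikes, unit_id="u0", baseline=()):
    """UnitRecording from explicit spike times.

    ``per_trial_spikes``: dict stimulus_id -> list (over repeats) of spike
    time lists, seconds from trial start.
    """
    by_id = {s.stimulus_id: s for s in stimuli}
    trials = [
        Trial(sid, rep, np.asarray(spikes, dtype=float), by_id[sid].trial_duration_s)
        for sid, reps in per_trial_spikes.items()
        for rep, spikes in enumerate(reps)
    ]
    return UnitRecording(
        unit_id=unit_id,
        bird_id="b0",
        group="ZF-ZF",
        trials=trials,
        baseline=np.asarray(baseline, dtype=float),
        stimulus_table=list(stimuli),
    )
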