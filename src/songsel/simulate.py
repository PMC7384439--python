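"""Synthetic MLd-like spike-train sessions.

Spike trains are drawn from an inhomogeneous Poisson process whose rate is

    lambda(t) = max(0, spont + drive(t)),
    drive(t)  = g * tuning(stim) * kernel(t - onset) * envelope(t - onset),

with ``g = response_gain`` scaled by the song-type gain (``con_gain`` for
conspecific, ``het_gain`` for heterospecific songs) and negated for
stimuli the unit is inhibited by.  Frequency tuning is a Gaussian in
log2-frequency around the unit's preferred frequency; for white noise and
songs it is averaged over the stimulus's frequency-band descriptor.
Temporal kernels implement the four response patterns seen in midbrain
units (onset, sustained, primary-like, primary-like with notch), applied
from each envelope syllable onset.  The pattern kernel shapes responses
to tones and white noise -- the probes the pattern taxonomy is defined
on; song responses are isomorphic, i.e. they follow the song's amplitude
envelope, which is how most midbrain units respond to song regardless of
their tone-probe pattern class.

The rearing hypothesis enters through the song-type gains: normally
reared birds (ZF-ZF) carry a conspecific gain advantage under the
``rearing_effect`` scenario, while cross-fostered birds (ZF-CF) respond
to both song types alike.  Under the ``null`` scenario both groups use
equal gains, making birds exchangeable across groups -- the property the
bird-level permutation test relies on.

Two sampling paths share the same rate model: :func:`simulate_trial`
draws full spike trains (1 ms piecewise-constant rate, exact given that
discretization), while :func:`simulate_rs_long_table` draws only the
window spike *counts* needed for Response Strength.  Because the total
count over a window of an inhomogeneous Poisson process is Poisson with
mean equal to the integrated rate, the fast path is an exact marginal of
the full one; it exists so that calibration studies with thousands of
replicate datasets are practical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .session_io import (
    BASELINE_DURATION_S,
    N_REPEATS,
    Session,
    Trial,
    UnitRecording,
)
from .stimuli import StimulusSpec, TONE_FREQS_HZ, make_stimulus_set, song_label

DT_S = 0.001  # rate-discretization step for spike sampling
KERNEL_TAU_S = 0.030  # onset-transient decay time constant
ONSET_AMP = 5.0
PL_PLATEAU = 1.0
PL_TRANSIENT = 2.5
NOTCH_WINDOW_S = (0.050, 0.100)  # suppressive dip after syllable onset
NOTCH_FACTOR = 0.05
MIN_TUNING_FREQ_HZ = 100.0  # lower integration bound for band tuning

PATTERNS = ("onset", "sustained", "primary_like", "primary_like_notch")
ISI_CHOICES_S = tuple(round(0.5 + 0.1 * k, 1) for k in range(11))  # 0.5 .. 1.5

#: Response gain at which pattern and best-frequency recovery are benchmarked.
HIGH_SNR_GAIN = 80.0


@dataclass(frozen=True)
class UnitParams:
    """Generative parameters of one simulated unit."""

    unit_id: str
    bird_id: str
    group: str  # "ZF-ZF" | "ZF-CF"
    spont_rate_hz: float
    bf_hz: float
    tuning_bandwidth_oct: float
    pattern: str
    response_gain: float
    con_gain: float = 1.0
    het_gain: float = 1.0
    inhibitory_stimuli: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.spont_rate_hz < 0 or self.response_gain < 0:
            raise ValueError("rates and gains must be non-negative")
        if min(self.con_gain, self.het_gain) < 0:
            raise ValueError("song-type gains must be non-negative")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class ScenarioConfig:
    """Study-condition configuration for a simulated multi-bird session.

    ``effect`` selects the generative scenario: ``"null"`` gives both
    groups identical song-type gains; ``"rearing_effect"`` gives ZF-ZF
    units a conspecific gain of ``con_gain_zfzf`` while ZF-CF units stay
    at parity.  All remaining fields are population hyperparameters; they
    are module defaults chosen to emulate midbrain response statistics
    (mostly silent or low-spontaneous units, low-frequency tuning, a
    sustained-dominated pattern mix, occasional inhibition), not measured
    quantities.
    """

    n_birds_per_group: int = 6
    units_per_bird: tuple[int, int] = (4, 10)
    seed: int = 0
    effect: str = "null"  # "null" | "rearing_effect"
    con_gain_zfzf: float = 1.3

    # spontaneous-rate mixture: point mass at zero, low-rate majority,
    # and a small tail of brisk units; group-independent so that the null
    # scenario keeps birds exchangeable across groups
    spont_zero_prob: float = 0.20
    spont_low_max_hz: float = 5.0
    spont_tail_prob: float = 0.08
    spont_tail_max_hz: float = 15.0

    # response-gain lognormal and frequency tuning
    gain_median: float = 40.0
    gain_log_sd: float = 0.5
    tuning_bandwidth_oct: float = 0.5
    bf_probs: tuple[float, ...] = (0.30, 0.32, 0.24, 0.08, 0.05, 0.01)

    pattern_probs: tuple[float, ...] = (0.20, 0.40, 0.25, 0.15)
    inhibition_prob: float = 0.10
    n_inhibitory: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.effect not in ("null", "rearing_effect"):
            raise ValueError(f"unknown effect scenario {self.effect!r}")
        if self.n_birds_per_group < 1:
            raise ValueError("need at least one bird per group")
        lo, hi = self.units_per_bird
        if lo < 1 or hi < lo:
            raise ValueError("invalid units_per_bird range")
        if not math.isclose(sum(self.bf_probs), 1.0, abs_tol=1e-9):
            raise ValueError("bf_probs must sum to 1")
        if not math.isclose(sum(self.pattern_probs), 1.0, abs_tol=1e-9):
            raise ValueError("pattern_probs must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("units_per_bird", "bf_probs", "pattern_probs", "n_inhibitory"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# rate model


def tuning_factor(params: UnitParams, stim: StimulusSpec) -> float:
    """Gaussian log-frequency tuning evaluated for one stimulus.

    Pure tones are evaluated at the tone frequency; broadband stimuli use
    the mean tuning over a log-spaced grid spanning the stimulus's
    aggregate frequency band (floored at 100 Hz so the log grid is
    well defined for descriptors that start at 0 Hz).
    """
    sigma = params.tuning_bandwidth_oct
    log_bf = math.log2(params.bf_hz)
    if stim.category == "TONE":
        x = math.log2(stim.tone_freq_hz) - log_bf
        return math.exp(-0.5 * (x / sigma) ** 2)
    lo, hi = stim.band_hz
    lo = max(lo, MIN_TUNING_FREQ_HZ)
    grid = np.linspace(math.log2(lo), math.log2(hi), 33)
    return float(np.mean(np.exp(-0.5 * ((grid - log_bf) / sigma) ** 2)))


def _kernel(pattern: str, dt_since_onset: np.ndarray) -> np.ndarray:
    """Temporal response kernel, evaluated within a syllable."""
    d = dt_since_onset
    if pattern == "onset":
        return ONSET_AMP * np.exp(-d / KERNEL_TAU_S)
    if pattern == "sustained":
        return np.ones_like(d)
    k = PL_PLATEAU + PL_TRANSIENT * np.exp(-d / KERNEL_TAU_S)
    if pattern == "primary_like_notch":
        dip = (d >= NOTCH_WINDOW_S[0]) & (d < NOTCH_WINDOW_S[1])
        k = np.where(dip, NOTCH_FACTOR * k, k)
    return k


@lru_cache(maxsize=512)
def _stimulus_shape(stim: StimulusSpec, pattern: str) -> np.ndarray:
    """Unit-gain drive shape over the stimulus window, on the DT_S grid."""
    n = int(round(stim.duration_s / DT_S))
    t = (np.arange(n) + 0.5) * DT_S
    shape = np.zeros(n)
    for syl in stim.envelope:
        m = (t >= syl.start_s) & (t < syl.end_s)
        shape[m] += syl.amplitude * _kernel(pattern, t[m] - syl.start_s)
    return shape


def _effective_pattern(params: UnitParams, stim: StimulusSpec) -> str:
    # song responses follow the amplitude envelope (isomorphic); the
    # pattern kernel applies to the tone/WN probes the taxonomy is built on
    return "sustained" if stim.category == "SONG" else params.pattern


def _song_type_gain(params: UnitParams, stim: StimulusSpec) -> float:
    if stim.song_type == "CON":
        return params.con_gain
    if stim.song_type == "HET":
        return params.het_gain
    return 1.0


def rate_profile(params: UnitParams, stim: StimulusSpec, dt: float = DT_S) -> np.ndarray:
    """Firing-rate profile over the full trial window, clamped at zero."""
    if dt != DT_S:
        raise ValueError("rate_profile is defined on the module grid DT_S")
    n_pre = int(round(stim.pre_silence_s / dt))
    n_post = int(round(stim.post_silence_s / dt))
    shape = _stimulus_shape(stim, _effective_pattern(params, stim))
    g = params.response_gain * tuning_factor(params, stim) * _song_type_gain(params, stim)
    if stim.stimulus_id in params.inhibitory_stimuli:
        g = -g
    rate = np.concatenate(
        [
            np.full(n_pre, params.spont_rate_hz),
            np.maximum(0.0, params.spont_rate_hz + g * shape),
            np.full(n_post, params.spont_rate_hz),
        ]
    )
    if not np.all(np.isfinite(rate)):
        raise ValueError(f"non-finite rate for {stim.stimulus_id}")
    return rate


def mean_stimulus_rate(params: UnitParams, stim: StimulusSpec) -> float:
    """Expected firing rate (spikes/s) during the stimulus period."""
    shape = _stimulus_shape(stim, _effective_pattern(params, stim))
    g = params.response_gain * tuning_factor(params, stim) * _song_type_gain(params, stim)
    if stim.stimulus_id in params.inhibitory_stimuli:
        g = -g
    return float(np.mean(np.maximum(0.0, params.spont_rate_hz + g * shape)))


def _spikes_from_counts(
    counts: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(np.arange(counts.size) * dt, counts)
    times = starts + rng.random(total) * dt
    return np.round(np.sort(times), 6)


def simulate_trial(
    params: UnitParams, stim: StimulusSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw one trial's spike train (seconds from trial start, sorted).

    Exact inhomogeneous Poisson sampling for the 1 ms piecewise-constant
    rate: per-bin counts are Poisson, spikes placed uniformly within
    their bin, then rounded to microsecond precision.
    """
    rate = rate_profile(params, stim)
    counts = rng.poisson(rate * DT_S)
    spikes = _spikes_from_counts(counts, DT_S, rng)
    window = stim.trial_duration_s
    return spikes[spikes < window]


# ---------------------------------------------------------------------------
# population draws


def draw_unit_params(
    rng: np.random.Generator,
    unit_id: str,
    bird_id: str,
    group: str,
    config: ScenarioConfig,
    stimulus_ids: tuple[str, ...],
    response_gain: Optional[float] = None,
) -> UnitParams:
    """Draw one unit's generative parameters from the population model."""
    u = rng.random()
    if u < config.spont_zero_prob:
        spont = 0.0
    elif u < config.spont_zero_prob + config.spont_tail_prob:
        spont = float(rng.uniform(config.spont_low_max_hz, config.spont_tail_max_hz))
    else:
        spont = float(rng.uniform(0.2, config.spont_low_max_hz))

    bf = float(rng.choice(TONE_FREQS_HZ, p=config.bf_probs))
    pattern = str(rng.choice(PATTERNS, p=config.pattern_probs))
    if response_gain is None:
        response_gain = float(
            config.gain_median * np.exp(rng.normal(0.0, config.gain_log_sd))
        )

    if config.effect == "rearing_effect" and group == "ZF-ZF":
        con_gain, het_gain = config.con_gain_zfzf, 1.0
    else:
        con_gain, het_gain = 1.0, 1.0

    inhibitory: frozenset[str] = frozenset()
    if rng.random() < config.inhibition_prob:
        k = int(rng.integers(config.n_inhibitory[0], config.n_inhibitory[1] + 1))
        inhibitory = frozenset(rng.choice(stimulus_ids, size=k, replace=False).tolist())

    return UnitParams(
        unit_id=unit_id,
        bird_id=bird_id,
        group=group,
        spont_rate_hz=spont,
        bf_hz=bf,
        tuning_bandwidth_oct=config.tuning_bandwidth_oct,
        pattern=pattern,
        response_gain=response_gain,
        con_gain=con_gain,
        het_gain=het_gain,
        inhibitory_stimuli=inhibitory,
    )


def _bird_layout(
    config: ScenarioConfig, rng: np.random.Generator
) -> list[tuple[str, str, int]]:
    """(bird_id, group, n_units) for every bird, in a fixed order."""
    layout = []
    for group, tag in (("ZF-ZF", "zfzf"), ("ZF-CF", "zfcf")):
        for b in range(1, config.n_birds_per_group + 1):
            lo, hi = config.units_per_bird
            n_units = int(rng.integers(lo, hi + 1))
            layout.append((f"{tag}-b{b}", group, n_units))
    return layout


def simulate_session(config: ScenarioConfig) -> Session:
    """Simulate a full multi-bird session of spike trains.

    Every unit receives all 19 stimuli, 15 repeats each (285 trials), in
    a randomized per-unit stimulus order with a per-sequence constant
    inter-stimulus interval drawn from 0.5--1.5 s in 0.1 s steps, plus a
    30 s baseline segment.  Fully reproducible from ``config.seed``; the
    generator ground truth is attached as ``session.truth``.
    """
    stimuli = make_stimulus_set(config.seed)
    stim_ids = tuple(s.stimulus_id for s in stimuli)
    ss = np.random.SeedSequence(config.seed)
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    layout = _bird_layout(config, layout_rng)

    units: list[UnitRecording] = []
    truth: dict[str, UnitParams] = {}
    unit_seeds = ss.spawn(sum(n for _, _, n in layout))
    k = 0
    for bird_id, group, n_units in layout:
        for j in range(1, n_units + 1):
            rng = np.random.default_rng(unit_seeds[k])
            k += 1
            unit_id = f"{bird_id}-u{j}"
            params = draw_unit_params(rng, unit_id, bird_id, group, config, stim_ids)
            order = [stim_ids[i] for i in rng.permutation(len(stim_ids))]
            isi = {sid: float(rng.choice(ISI_CHOICES_S)) for sid in order}
            trials: list[Trial] = []
            for sid in order:
                stim = stimuli[stim_ids.index(sid)]
                for rep in range(N_REPEATS):
                    trials.append(
                        Trial(
                            stimulus_id=sid,
                            repeat_index=rep,
                            spikes=simulate_trial(params, stim, rng),
                            trial_duration_s=stim.trial_duration_s,
                        )
                    )
            n_base = rng.poisson(params.spont_rate_hz * BASELINE_DURATION_S)
            baseline = np.round(
                np.sort(rng.random(n_base) * BASELINE_DURATION_S), 6
            )
            units.append(
                UnitRecording(
                    unit_id=unit_id,
                    bird_id=bird_id,
                    group=group,
                    trials=trials,
                    baseline=baseline,
                    stimulus_table=stimuli,
                    presentation_order=order,
                    isi_by_stimulus=isi,
                )
            )
            truth[unit_id] = params
    return Session(stimuli=stimuli, units=units, truth=truth)


# ---------------------------------------------------------------------------
# fast Response-Strength-level sampling


def simulate_rs_long_table(config: ScenarioConfig) -> pd.DataFrame:
    """Draw per-(unit, song) Response Strength directly, skipping spike times.

    Uses the identical rate model as :func:`simulate_trial`: the evoked
    count per trial is Poisson with mean ``mean_stimulus_rate * duration``
    and the pre-stimulus count is Poisson with mean ``spont * 0.5``, so
    per-trial RS values have exactly the distribution the spike-train path
    induces.  Returns a long table with one row per unit x song stimulus
    (columns: bird_id, group, unit_id, stimulus_id, song_id, song_type,
    direction, mean_rs, var_rs, n).
    """
    stimuli = make_stimulus_set(config.seed)
    songs = [s for s in stimuli if s.category == "SONG"]
    ss = np.random.SeedSequence(config.seed)
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    layout = _bird_layout(config, layout_rng)
    rng = np.random.default_rng(ss.spawn(2)[1])
    stim_ids = tuple(s.stimulus_id for s in stimuli)

    rows = []
    for bird_id, group, n_units in layout:
        for j in range(1, n_units + 1):
            unit_id = f"{bird_id}-u{j}"
            params = draw_unit_params(rng, unit_id, bird_id, group, config, stim_ids)
            for stim in songs:
                rate = mean_stimulus_rate(params, stim)
                esr = rng.poisson(rate * stim.duration_s, N_REPEATS) / stim.duration_s
                ssr = rng.poisson(params.spont_rate_hz * 0.5, N_REPEATS) / 0.5
                rs = esr - ssr
                rows.append(
                    (
                        bird_id,
                        group,
                        unit_id,
                        stim.stimulus_id,
                        song_label(stim.stimulus_id),
                        stim.song_type,
                        stim.direction,
                        float(rs.mean()),
                        float(rs.var(ddof=1)),
                        N_REPEATS,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "bird_id",
            "group",
            "unit_id",
            "stimulus_id",
            "song_id",
            "song_type",
            "direction",
            "mean_rs",
            "var_rs",
            "n",
        ],
    )
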