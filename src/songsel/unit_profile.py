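"""Per-unit response properties.

Implements the basic single-unit characterization chain: spontaneous
rate from the first 20 s of the 30 s baseline; 20 ms-bin peristimulus
time histograms; the "auditory" response criterion (any stimulus-period
bin exceeding the mean + 5 SD of the pre-stimulus baseline bins);
response sign including inhibition; best frequency from the tone
responses; and a rule-based version of the four temporal response
patterns (onset, sustained, primary-like, primary-like with notch).

The 5 SD criterion deliberately misses inhibited responses: a unit whose
only effect is suppression below its spontaneous rate never crosses an
excitatory threshold.  :func:`response_sign` therefore adds an explicit
inhibition test, which is itself blind for units with no spontaneous
activity -- there is nothing to suppress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .session_io import UnitRecording
from .stimuli import StimulusSpec, TONE_FREQS_HZ, stimulus_index

PSTH_BIN_S = 0.020
SPONT_WINDOW_S = 20.0
CRITERION_N_SD = 5.0
CRITERION_FLOOR_COUNT = 3.0
INHIBITION_N_SD = 2.0
PATTERN_LABELS = (
    "onset",
    "sustained",
    "primary_like",
    "primary_like_notch",
    "unclassified",
)


@dataclass
class PSTH:
    """Trial-aligned 20 ms-bin histogram for one unit x stimulus.

    ``count_per_bin`` sums spikes across repeats; ``rate_per_bin`` is the
    across-repeat average rate, ``count / (n_repeats * bin_width)``.
    Bins tile the half-open trial window ``[0, trial_duration)``; the
    last bin may extend past the window and is then only partially
    covered by data.
    """

    bin_edges: np.ndarray
    count_per_bin: np.ndarray
    n_repeats: int
    stim_onset_s: float
    stim_duration_s: float
    bin_width_s: float = PSTH_BIN_S

    @property
    def rate_per_bin(self) -> np.ndarray:
        return self.count_per_bin / (self.n_repeats * self.bin_width_s)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.bin_edges[:-1]

    def stimulus_bins(self) -> np.ndarray:
        """Boolean mask of bins overlapping the stimulus period."""
        on, off = self.stim_onset_s, self.stim_onset_s + self.stim_duration_s
        return (self.bin_starts < off - 1e-9) & (self.bin_edges[1:] > on + 1e-9)

    def baseline_bins(self) -> np.ndarray:
        """Boolean mask of bins fully inside the pre-stimulus silence."""
        return self.bin_edges[1:] <= self.stim_onset_s + 1e-9


@dataclass
class CriterionResult:
    stimulus_id: str
    passed: bool
    threshold_count: float
    baseline_mean: float
    baseline_sd: float
    peak_count: float
    mode: str


@dataclass
class UnitProfile:
    unit_id: str
    bird_id: str
    group: str
    spont_rate_hz: float
    is_auditory: bool
    responsive: dict[str, str]  # stimulus_id -> excited | inhibited | none
    evoked_rate_hz: dict[str, float]  # mean rate during stimulus period
    bf_hz: Optional[float]
    pattern_bf: str
    pattern_wn: str
    missing_stimuli: list[str] = field(default_factory=list)

    @property
    def n_songs_excited(self) -> int:
        return sum(
            1
            for sid, sign in self.responsive.items()
            if sign == "excited" and sid.startswith(("CON", "HET"))
        )


def spontaneous_rate(unit: UnitRecording) -> float:
    """Spikes/s over the first 20 s of the baseline segment."""
    if unit.baseline is None:
        raise ValueError(f"unit {unit.unit_id}: no baseline segment")
    base = np.asarray(unit.baseline)
    return float(np.count_nonzero(base < SPONT_WINDOW_S)) / SPONT_WINDOW_S


def compute_psth(unit: UnitRecording, stimulus_id: str) -> PSTH:
    """20 ms-bin PSTH over the full trial window of one stimulus."""
    stim = stimulus_index(unit.stimulus_table)[stimulus_id]
    trials = unit.trials_for(stimulus_id)
    if not trials:
        raise ValueError(f"unit {unit.unit_id}: no trials for {stimulus_id}")
    window = stim.trial_duration_s
    n_bins = int(math.ceil(window / PSTH_BIN_S - 1e-9))
    edges = np.arange(n_bins + 1) * PSTH_BIN_S
    counts = np.zeros(n_bins)
    for t in trials:
        c, _ = np.histogram(t.spikes, bins=edges)
        counts += c
    return PSTH(
        bin_edges=edges,
        count_per_bin=counts,
        n_repeats=len(trials),
        stim_onset_s=stim.pre_silence_s,
        stim_duration_s=stim.duration_s,
    )


def auditory_criterion(
    unit: UnitRecording, stimulus_id: str, baseline_stat: str = "pooled"
) -> CriterionResult:
    """Excitatory response criterion for one unit x stimulus.

    The baseline distribution is formed from every trial's 20 ms bins of
    the 500 ms pre-stimulus silence, pooled across the repeats (25 bins x
    n_repeats values), and the unit passes when any stimulus-period bin
    exceeds mean + 5 SD.  Two scalings of the comparison are available:

    ``"pooled"`` (default)
        The threshold is expressed on the scale of across-repeat summed
        bin counts (a sum of n independent baseline bins has mean n*mu
        and SD sqrt(n)*sigma) and compared against the summed
        stimulus-bin counts of the PSTH.
    ``"per_trial_rate"``
        The threshold stays on the single-trial rate scale (mean + 5 SD
        of the per-trial bin rates) and is compared against the PSTH bin
        rates; because single-trial bins are far noisier than the
        across-repeat average, this variant is very conservative.

    In both modes a floor guards the degenerate silent baseline (SD = 0):
    the effective count threshold is never below 3 summed spikes, so a
    single stray spike cannot make a silent unit "auditory" while a
    response repeated across trials still can.
    """
    psth = compute_psth(unit, stimulus_id)
    base_mask = psth.baseline_bins()
    stim_mask = psth.stimulus_bins()
    if not base_mask.any():
        raise ValueError(f"{stimulus_id}: no pre-stimulus window")

    trials = unit.trials_for(stimulus_id)
    n_rep = len(trials)
    edges = psth.bin_edges[: int(base_mask.sum()) + 1]
    per_trial = np.concatenate(
        [np.histogram(t.spikes, bins=edges)[0] for t in trials]
    ).astype(float)
    mean, sd = float(per_trial.mean()), float(per_trial.std(ddof=1))

    if baseline_stat == "pooled":
        # distribution of across-repeat summed bin counts implied by the
        # per-trial bin statistics: a sum of n_rep independent bins has
        # mean n_rep * mu and SD sqrt(n_rep) * sigma
        threshold = max(
            n_rep * mean + CRITERION_N_SD * math.sqrt(n_rep) * sd,
            CRITERION_FLOOR_COUNT,
        )
        peak = float(psth.count_per_bin[stim_mask].max())
        passed = peak >= threshold - 1e-12
    elif baseline_stat == "per_trial_rate":
        rates = per_trial / PSTH_BIN_S
        rate_thr = float(rates.mean()) + CRITERION_N_SD * float(rates.std(ddof=1))
        floor_rate = CRITERION_FLOOR_COUNT / (n_rep * PSTH_BIN_S)
        threshold = max(rate_thr, floor_rate)
        peak = float(psth.rate_per_bin[stim_mask].max())
        passed = peak >= threshold - 1e-12
    else:
        raise ValueError(f"unknown baseline_stat {baseline_stat!r}")

    return CriterionResult(
        stimulus_id=stimulus_id,
        passed=bool(passed),
        threshold_count=threshold,
        baseline_mean=mean,
        baseline_sd=sd,
        peak_count=peak,
        mode=baseline_stat,
    )


def is_auditory(unit: UnitRecording, baseline_stat: str = "pooled") -> bool:
    """True when the unit reaches criterion for at least one stimulus."""
    return any(
        auditory_criterion(unit, sid, baseline_stat).passed
        for sid in unit.recorded_stimuli()
    )


def _per_trial_window_rates(
    unit: UnitRecording, stimulus_id: str
) -> tuple[np.ndarray, np.ndarray, float]:
    stim = stimulus_index(unit.stimulus_table)[stimulus_id]
    trials = unit.trials_for(stimulus_id)
    pre = stim.pre_silence_s
    off = pre + stim.duration_s
    pre_rates = np.array(
        [np.count_nonzero(t.spikes < pre) / pre for t in trials]
    )
    stim_rates = np.array(
        [
            np.count_nonzero((t.spikes >= pre) & (t.spikes < off)) / stim.duration_s
            for t in trials
        ]
    )
    return pre_rates, stim_rates, stim.duration_s


def response_sign(
    unit: UnitRecording, stimulus_id: str, baseline_stat: str = "pooled"
) -> str:
    """Classify the response as excited, inhibited or none.

    Excitation is the 5 SD criterion.  Inhibition requires the mean
    stimulus-period rate to fall at least 2 standard errors (the SD of
    the per-trial pre-stimulus rates scaled by sqrt(n)) below the mean
    pre-stimulus rate, and is only detectable in units with nonzero
    spontaneous activity -- a silent unit has nothing to suppress.
    """
    if auditory_criterion(unit, stimulus_id, baseline_stat).passed:
        return "excited"
    if spontaneous_rate(unit) <= 0:
        return "none"
    pre_rates, stim_rates, _ = _per_trial_window_rates(unit, stimulus_id)
    if len(pre_rates) < 2:
        return "none"
    sem = pre_rates.std(ddof=1) / math.sqrt(len(pre_rates))
    cut = pre_rates.mean() - INHIBITION_N_SD * sem
    if stim_rates.mean() < cut:
        return "inhibited"
    return "none"


def best_frequency(
    unit: UnitRecording, baseline_stat: str = "pooled"
) -> Optional[float]:
    """Tone frequency with the largest mean evoked rate among excitatory
    tone responses; ties go to the lowest frequency; None when no tone
    excites the unit."""
    best: Optional[tuple[float, float]] = None  # (rate, freq)
    tones = sorted(
        (s for s in unit.stimulus_table if s.category == "TONE"),
        key=lambda s: s.tone_freq_hz,
    )
    for stim in tones:
        if not unit.trials_for(stim.stimulus_id):
            continue
        if response_sign(unit, stim.stimulus_id, baseline_stat) != "excited":
            continue
        _, stim_rates, _ = _per_trial_window_rates(unit, stim.stimulus_id)
        rate = float(stim_rates.mean())
        if best is None or rate > best[0]:  # strict: ties keep lower freq
            best = (rate, stim.tone_freq_hz)
    return None if best is None else best[1]


def classify_temporal_pattern(psth: PSTH, spont_rate_hz: float) -> str:
    """Deterministic version of the four-way PSTH shape taxonomy.

    With ``early`` the mean rate in the first 100 ms after stimulus
    onset, ``steady`` the mean rate from 100 ms to stimulus offset and
    ``peak`` the largest bin rate within 150 ms of onset:

    * onset: ``early >= 2 x spont`` and ``steady`` below the midpoint of
      spont and ``early``;
    * primary-like: ``peak >= 2 x steady`` with a plateau clearly above
      spont; with notch if any bin within 150 ms after the peak dips
      below half the plateau;
    * sustained: suprathreshold plateau with ``peak < 2 x steady``;
    * otherwise unclassified.

    A 1 spike/s floor stands in for spont in the ratio tests so that
    silent units do not divide by zero.
    """
    on = psth.stim_onset_s
    off = on + psth.stim_duration_s
    rates = psth.rate_per_bin
    starts = psth.bin_starts

    early_m = (starts >= on - 1e-9) & (starts < on + 0.1 - 1e-9)
    steady_m = (starts >= on + 0.1 - 1e-9) & (psth.bin_edges[1:] <= off + 1e-9)
    peak_m = (starts >= on - 1e-9) & (starts < on + 0.15 - 1e-9)
    if not early_m.any() or not steady_m.any():
        return "unclassified"
    early = float(rates[early_m].mean())
    steady = float(rates[steady_m].mean())
    peak_idx = int(np.flatnonzero(peak_m)[np.argmax(rates[peak_m])])
    peak = float(rates[peak_idx])
    peak_t = float(starts[peak_idx])

    s0 = max(spont_rate_hz, 1.0)
    if early < 2.0 * s0 and steady < 2.0 * s0:
        return "unclassified"
    if early >= 2.0 * s0 and steady < 0.5 * (spont_rate_hz + early):
        return "onset"
    if peak >= 2.0 * steady and steady > spont_rate_hz + 1.0:
        dip_m = (
            (starts > peak_t + 1e-9)
            & (starts < peak_t + 0.15 - 1e-9)
            & (psth.bin_edges[1:] <= off + 1e-9)
        )
        if dip_m.any() and rates[dip_m].min() < 0.5 * steady:
            return "primary_like_notch"
        return "primary_like"
    if steady >= 2.0 * s0:
        return "sustained"
    return "unclassified"


def unit_profile(unit: UnitRecording, baseline_stat: str = "pooled") -> UnitProfile:
    """Full basic characterization of one unit."""
    spont = spontaneous_rate(unit)
    responsive: dict[str, str] = {}
    evoked: dict[str, float] = {}
    for sid in unit.recorded_stimuli():
        responsive[sid] = response_sign(unit, sid, baseline_stat)
        _, stim_rates, _ = _per_trial_window_rates(unit, sid)
        evoked[sid] = float(stim_rates.mean())
    auditory = any(v == "excited" for v in responsive.values())

    bf = best_frequency(unit, baseline_stat)
    pattern_bf = "unclassified"
    if bf is not None:
        bf_id = f"TONE-{int(bf) // 1000}"
        pattern_bf = classify_temporal_pattern(compute_psth(unit, bf_id), spont)
    pattern_wn = "unclassified"
    if "WN" in responsive and responsive["WN"] == "excited":
        pattern_wn = classify_temporal_pattern(compute_psth(unit, "WN"), spont)

    return UnitProfile(
        unit_id=unit.unit_id,
        bird_id=unit.bird_id,
        group=unit.group,
        spont_rate_hz=spont,
        is_auditory=auditory,
        responsive=responsive,
        evoked_rate_hz=evoked,
        bf_hz=bf,
        pattern_bf=pattern_bf,
        pattern_wn=pattern_wn,
        missing_stimuli=unit.missing_stimuli(),
    )


# ---------------------------------------------------------------------------
# population summaries


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else float("nan")


def population_summary(profiles: list[UnitProfile]) -> dict[str, pd.DataFrame]:
    """Group-level summary tables of simple-stimulus responses.

    Returns tables keyed ``tone_wn_response`` (percent of units excited
    by WN and each tone, plus units excited by none of them),
    ``bf_distribution``, ``pattern_distribution`` (per probe),
    ``stimulus_class_combinations`` (song-only / tones+songs / WN+songs /
    all three, and which of tones vs WN drives the stronger response) and
    ``songs_responded`` (how many of the 12 songs excite each unit).
    """
    if not profiles:
        raise ValueError("no unit profiles")
    groups = sorted({p.group for p in profiles})
    simple_ids = ["WN"] + [f"TONE-{f // 1000}" for f in TONE_FREQS_HZ]

    def grp(g):
        return [p for p in profiles if p.group == g]

    rows = {}
    for g in groups:
        ps = grp(g)
        n = len(ps)
        row = {
            sid: _pct(sum(p.responsive.get(sid) == "excited" for p in ps), n)
            for sid in simple_ids
        }
        row["none"] = _pct(
            sum(
                all(p.responsive.get(sid) != "excited" for sid in simple_ids)
                for p in ps
            ),
            n,
        )
        row["n_units"] = n
        rows[g] = row
    tone_wn = pd.DataFrame(rows).T

    bf_rows = {}
    for g in groups:
        ps = grp(g)
        n = len(ps)
        bf_rows[g] = {
            f"{f // 1000} kHz": _pct(sum(p.bf_hz == f for p in ps), n)
            for f in TONE_FREQS_HZ
        }
        bf_rows[g]["no BF"] = _pct(sum(p.bf_hz is None for p in ps), n)
    bf_dist = pd.DataFrame(bf_rows).T

    pat_rows = {}
    for g in groups:
        ps = grp(g)
        n = len(ps)
        for probe, attr in (("BF", "pattern_bf"), ("WN", "pattern_wn")):
            pat_rows[(g, probe)] = {
                lab: _pct(sum(getattr(p, attr) == lab for p in ps), n)
                for lab in PATTERN_LABELS
            }
    pattern_dist = pd.DataFrame(pat_rows).T

    combo_rows = {}
    for g in groups:
        ps = grp(g)
        n = len(ps)

        def has(p, kind):
            if kind == "song":
                return p.n_songs_excited > 0
            if kind == "wn":
                return p.responsive.get("WN") == "excited"
            return any(
                p.responsive.get(f"TONE-{f // 1000}") == "excited"
                for f in TONE_FREQS_HZ
            )

        def tone_rate(p):
            rates = [
                p.evoked_rate_hz.get(f"TONE-{f // 1000}", 0.0) for f in TONE_FREQS_HZ
            ]
            return max(rates) if rates else 0.0

        combo_rows[g] = {
            "songs only": _pct(
                sum(has(p, "song") and not has(p, "wn") and not has(p, "tone") for p in ps), n
            ),
            "tones and songs": _pct(
                sum(has(p, "song") and has(p, "tone") and not has(p, "wn") for p in ps), n
            ),
            "WN and songs": _pct(
                sum(has(p, "song") and has(p, "wn") and not has(p, "tone") for p in ps), n
            ),
            "all 3": _pct(
                sum(has(p, "song") and has(p, "wn") and has(p, "tone") for p in ps), n
            ),
            "tones > WN": _pct(
                sum(tone_rate(p) > p.evoked_rate_hz.get("WN", 0.0) for p in ps), n
            ),
            "WN > tones": _pct(
                sum(p.evoked_rate_hz.get("WN", 0.0) >= tone_rate(p) for p in ps), n
            ),
        }
    combos = pd.DataFrame(combo_rows).T

    song_rows = {}
    for g in groups:
        ps = grp(g)
        n = len(ps)
        song_rows[g] = {
            k: _pct(sum(p.n_songs_excited == k for p in ps), n) for k in range(13)
        }
    songs = pd.DataFrame(song_rows).T

    return {
        "tone_wn_response": tone_wn,
        "bf_distribution": bf_dist,
        "pattern_distribution": pattern_dist,
        "stimulus_class_combinations": combos,
        "songs_responded": songs,
    }
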