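"""Stimulus set construction.

A recording session probes each unit with 19 stimuli: one white-noise
burst, six pure tones (1--6 kHz), and twelve songs -- three conspecific
(zebra finch, CON) and three heterospecific (Bengalese finch, HET) songs,
each played forward (FOR) and time-reversed (REV).  Every stimulus is
padded with 500 ms of silence before and after the sound.

Songs are represented as abstract amplitude envelopes, not audio: a
sequence of piecewise-constant syllables, each with an amplitude and a
dominant-frequency band.  That is all the downstream rate model needs.
Reversal mirrors the envelope in time, which preserves spectral content
while inverting temporal structure -- exactly the manipulation the
forward/reverse comparison is about.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

TONE_FREQS_HZ: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000, 6000)

#: Conspecific (zebra finch) song durations span this interval (seconds).
CON_DURATION_RANGE_S: tuple[float, float] = (1.816, 2.691)
#: Heterospecific (Bengalese finch) song durations span this interval.
HET_DURATION_RANGE_S: tuple[float, float] = (1.940, 3.091)

DEFAULT_PRE_SILENCE_S = 0.5
DEFAULT_POST_SILENCE_S = 0.5
TONE_RAMP_S = 0.150  # on/off cosine ramp of the recorded tones; metadata only
N_STIMULI = 19
N_SONGS_PER_TYPE = 3


@dataclass(frozen=True)
class Syllable:
    """One piecewise-constant envelope segment within a stimulus.

    Times are seconds from *stimulus* onset (not trial onset).  The
    frequency band is the dominant spectral content of the segment and is
    what frequency tuning acts on.
    """

    start_s: float
    end_s: float
    amplitude: float
    f_lo_hz: float
    f_hi_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StimulusSpec:
    """Identity, category and timing envelope of one stimulus."""

    stimulus_id: str
    category: str  # "WN" | "TONE" | "SONG"
    duration_s: float
    tone_freq_hz: Optional[float] = None
    song_type: Optional[str] = None  # "CON" | "HET"
    direction: Optional[str] = None  # "FOR" | "REV"
    pre_silence_s: float = DEFAULT_PRE_SILENCE_S
    post_silence_s: float = DEFAULT_POST_SILENCE_S
    envelope: tuple[Syllable, ...] = field(default_factory=tuple)
    ramp_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"{self.stimulus_id}: duration must be positive")
        if self.category == "SONG" and (self.song_type is None or self.direction is None):
            raise ValueError(f"{self.stimulus_id}: SONG stimuli need song_type and direction")
        if not self.envelope:
            raise ValueError(f"{self.stimulus_id}: exactly one envelope is required")

    @property
    def trial_duration_s(self) -> float:
        """Total trial window: pre-silence + stimulus + post-silence."""
        return self.pre_silence_s + self.duration_s + self.post_silence_s

    @property
    def band_hz(self) -> tuple[float, float]:
        """Aggregate frequency-band descriptor across the envelope."""
        los = [s.f_lo_hz for s in self.envelope]
        his = [s.f_hi_hz for s in self.envelope]
        return (min(los), max(his))

    def mirrored(self, stimulus_id: str, direction: str) -> "StimulusSpec":
        """Time-mirrored copy (the REV version of a FOR song)."""
        d = self.duration_s
        syls = tuple(
            sorted(
                (
                    Syllable(
                        start_s=d - s.end_s,
                        end_s=d - s.start_s,
                        amplitude=s.amplitude,
                        f_lo_hz=s.f_lo_hz,
                        f_hi_hz=s.f_hi_hz,
                    )
                    for s in self.envelope
                ),
                key=lambda s: s.start_s,
            )
        )
        return replace(self, stimulus_id=stimulus_id, direction=direction, envelope=syls)

    def envelope_value(self, t_s: np.ndarray) -> np.ndarray:
        """Amplitude at times ``t_s`` (seconds from stimulus onset)."""
        out = np.zeros_like(np.asarray(t_s, dtype=float))
        for s in self.envelope:
            m = (t_s >= s.start_s) & (t_s < s.end_s)
            out[m] = s.amplitude
        return out


#: Time-averaged envelope amplitude every song is normalized to, so that a
#: song's mean drive depends on the unit, not on its syllable bookkeeping.
SONG_MEAN_AMPLITUDE = 0.5


def _normalize_song(syls: list[Syllable], duration_s: float) -> tuple[Syllable, ...]:
    total = sum(s.amplitude * s.duration_s for s in syls)
    scale = SONG_MEAN_AMPLITUDE * duration_s / total
    return tuple(
        Syllable(s.start_s, s.end_s, s.amplitude * scale, s.f_lo_hz, s.f_hi_hz)
        for s in syls
    )


def _con_syllables(rng: np.random.Generator, duration_s: float) -> tuple[Syllable, ...]:
    # Zebra-finch-like motif: 50-200 ms syllables (harmonic stacks spanning a
    # broad low band) separated by short gaps.
    syls: list[Syllable] = []
    t = 0.0
    while t < duration_s - 0.02:
        length = min(rng.uniform(0.05, 0.20), duration_s - t)
        f_lo = rng.uniform(500.0, 900.0)
        f_hi = min(f_lo + rng.uniform(2000.0, 5000.0), 8000.0)
        syls.append(Syllable(t, t + length, rng.uniform(0.6, 1.0), f_lo, f_hi))
        t += length + rng.uniform(0.02, 0.08)
    return _normalize_song(syls, duration_s)


def _het_syllables(rng: np.random.Generator, duration_s: float) -> tuple[Syllable, ...]:
    # Bengalese-finch-like trains of brief trill syllables: individually
    # narrow bands whose centres wander over the same overall range the
    # conspecific songs occupy, so both song types cover a similar
    # aggregate band.
    syls: list[Syllable] = []
    t = 0.0
    while t < duration_s - 0.01:
        length = min(rng.uniform(0.02, 0.06), duration_s - t)
        f_lo = rng.uniform(500.0, 4000.0)
        f_hi = min(f_lo + rng.uniform(500.0, 2000.0), 6000.0)
        syls.append(Syllable(t, t + length, rng.uniform(0.6, 1.0), f_lo, f_hi))
        t += length + rng.uniform(0.01, 0.04)
    return _normalize_song(syls, duration_s)


def make_stimulus_set(seed: int) -> list[StimulusSpec]:
    """Build the 19-stimulus protocol set.

    Returns white noise (1 s, 0--10 kHz), six 1 s pure tones at 1--6 kHz
    (150 ms ramps recorded as metadata), and 3 CON + 3 HET songs each in
    FOR and REV direction.  Song durations are drawn uniformly within the
    species-specific ranges; each REV envelope is the exact time mirror of
    its FOR counterpart.
    """
    rng = np.random.default_rng(seed)
    stimuli: list[StimulusSpec] = [
        StimulusSpec(
            stimulus_id="WN",
            category="WN",
            duration_s=1.0,
            envelope=(Syllable(0.0, 1.0, 1.0, 0.0, 10_000.0),),
        )
    ]
    for f in TONE_FREQS_HZ:
        stimuli.append(
            StimulusSpec(
                stimulus_id=f"TONE-{f // 1000}",
                category="TONE",
                duration_s=1.0,
                tone_freq_hz=float(f),
                ramp_s=TONE_RAMP_S,
                envelope=(Syllable(0.0, 1.0, 1.0, float(f), float(f)),),
            )
        )
    for song_type, (lo, hi), maker in (
        ("CON", CON_DURATION_RANGE_S, _con_syllables),
        ("HET", HET_DURATION_RANGE_S, _het_syllables),
    ):
        for i in range(1, N_SONGS_PER_TYPE + 1):
            dur = float(rng.uniform(lo, hi))
            fwd = StimulusSpec(
                stimulus_id=f"{song_type}-{i}-FOR",
                category="SONG",
                duration_s=dur,
                song_type=song_type,
                direction="FOR",
                envelope=maker(rng, dur),
            )
            stimuli.append(fwd)
            stimuli.append(fwd.mirrored(f"{song_type}-{i}-REV", "REV"))
    assert len(stimuli) == N_STIMULI
    return stimuli


def song_label(stimulus_id: str) -> str:
    """``"CON-1-FOR"`` -> ``"CON-1"`` (song identity without direction)."""
    parts = stimulus_id.rsplit("-", 1)
    return parts[0]


def stimulus_index(stimuli: list[StimulusSpec]) -> dict[str, StimulusSpec]:
    return {s.stimulus_id: s for s in stimuli}
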