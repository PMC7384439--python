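"""On-disk session format and in-memory session model.

A session directory contains plain-text files only:

``manifest.json``
    Birds, units, per-unit trial bookkeeping (stimulus -> number of
    repeats), completeness flags and presentation metadata.
``stimuli.json``
    The stimulus specifications, including envelopes.
``spikes.csv``
    One row per spike: ``unit_id,stimulus_id,repeat_index,spike_time_s``.
``baseline.csv``
    One row per baseline spike: ``unit_id,spike_time_s``.

Spike times are seconds from trial start (t = 0 at trial start, stimulus
onset at ``pre_silence_s``), written at microsecond precision, and all
intervals are half-open ``[a, b)``.  Units with missing stimuli are legal
and flagged rather than rejected: real datasets contain such units (the
study this format serves retained a unit missing one song).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .stimuli import StimulusSpec, Syllable, stimulus_index

FORMAT_VERSION = 1
TIME_PRECISION_S = 1e-6
N_REPEATS = 15
BASELINE_DURATION_S = 30.0


class SessionFormatError(ValueError):
    """Raised when a session directory violates the schema."""


@dataclass
class Trial:
    """Spike train of one stimulus repeat, times relative to trial start."""

    stimulus_id: str
    repeat_index: int
    spikes: np.ndarray
    trial_duration_s: float

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)
        if self.repeat_index < 0 or self.repeat_index >= N_REPEATS:
            raise SessionFormatError(
                f"repeat_index {self.repeat_index} outside [0, {N_REPEATS})"
            )
        if self.spikes.size and (
            self.spikes.min() < 0 or self.spikes.max() >= self.trial_duration_s
        ):
            raise SessionFormatError(
                f"{self.stimulus_id} rep {self.repeat_index}: spikes outside "
                f"[0, {self.trial_duration_s})"
            )
        self.spikes = np.sort(self.spikes)


@dataclass
class UnitRecording:
    """All trials of one unit plus its 30 s baseline segment."""

    unit_id: str
    bird_id: str
    group: str  # "ZF-ZF" | "ZF-CF"
    trials: list[Trial]
    baseline: np.ndarray
    stimulus_table: list[StimulusSpec]
    presentation_order: Optional[list[str]] = None
    isi_by_stimulus: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        self.baseline = np.sort(np.asarray(self.baseline, dtype=float))
        known = {s.stimulus_id for s in self.stimulus_table}
        seen: set[tuple[str, int]] = set()
        for t in self.trials:
            if t.stimulus_id not in known:
                raise SessionFormatError(
                    f"unit {self.unit_id}: trial references unknown stimulus "
                    f"{t.stimulus_id!r}"
                )
            key = (t.stimulus_id, t.repeat_index)
            if key in seen:
                raise SessionFormatError(
                    f"unit {self.unit_id}: duplicate trial {key}"
                )
            seen.add(key)

    def trials_for(self, stimulus_id: str) -> list[Trial]:
        out = [t for t in self.trials if t.stimulus_id == stimulus_id]
        out.sort(key=lambda t: t.repeat_index)
        return out

    def recorded_stimuli(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.stimulus_id not in seen:
                seen.append(t.stimulus_id)
        return seen

    def missing_stimuli(self) -> list[str]:
        have = set(self.recorded_stimuli())
        return [s.stimulus_id for s in self.stimulus_table if s.stimulus_id not in have]

    @property
    def is_complete(self) -> bool:
        if self.missing_stimuli():
            return False
        return all(len(self.trials_for(s)) == N_REPEATS for s in self.recorded_stimuli())


@dataclass
class Session:
    """A multi-bird dataset: shared stimulus table plus unit recordings.

    ``truth`` optionally carries generator ground truth (unit parameters)
    for simulated sessions; it is never serialized.
    """

    stimuli: list[StimulusSpec]
    units: list[UnitRecording]
    truth: Optional[dict] = field(default=None, repr=False)

    def unit(self, unit_id: str) -> UnitRecording:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def birds(self) -> dict[str, str]:
        """bird_id -> group, in first-appearance order."""
        out: dict[str, str] = {}
        for u in self.units:
            out.setdefault(u.bird_id, u.group)
        return out


# ---------------------------------------------------------------------------
# serialization


def _stimulus_to_dict(s: StimulusSpec) -> dict:
    return {
        "stimulus_id": s.stimulus_id,
        "category": s.category,
        "duration_s": s.duration_s,
        "tone_freq_hz": s.tone_freq_hz,
        "song_type": s.song_type,
        "direction": s.direction,
        "pre_silence_s": s.pre_silence_s,
        "post_silence_s": s.post_silence_s,
        "ramp_s": s.ramp_s,
        "envelope": [
            {
                "start_s": y.start_s,
                "end_s": y.end_s,
                "amplitude": y.amplitude,
                "f_lo_hz": y.f_lo_hz,
                "f_hi_hz": y.f_hi_hz,
            }
            for y in s.envelope
        ],
    }


def _stimulus_from_dict(d: dict) -> StimulusSpec:
    return StimulusSpec(
        stimulus_id=d["stimulus_id"],
        category=d["category"],
        duration_s=d["duration_s"],
        tone_freq_hz=d.get("tone_freq_hz"),
        song_type=d.get("song_type"),
        direction=d.get("direction"),
        pre_silence_s=d.get("pre_silence_s", 0.5),
        post_silence_s=d.get("post_silence_s", 0.5),
        ramp_s=d.get("ramp_s"),
        envelope=tuple(Syllable(**y) for y in d["envelope"]),
    )


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session directory; returns the manifest path.

    Lossless at microsecond time precision.  Incomplete units are written
    as-is with ``complete: false`` and their missing stimuli listed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "stimuli.json", "w") as fh:
        json.dump([_stimulus_to_dict(s) for s in session.stimuli], fh, indent=1)

    spike_rows: list[str] = ["unit_id,stimulus_id,repeat_index,spike_time_s"]
    base_rows: list[str] = ["unit_id,spike_time_s"]
    units_meta = []
    for u in session.units:
        n_trials = {}
        for t in u.trials:
            n_trials[t.stimulus_id] = max(n_trials.get(t.stimulus_id, 0), t.repeat_index + 1)
            for sp in t.spikes:
                spike_rows.append(f"{u.unit_id},{t.stimulus_id},{t.repeat_index},{sp:.6f}")
        for sp in u.baseline:
            base_rows.append(f"{u.unit_id},{sp:.6f}")
        units_meta.append(
            {
                "unit_id": u.unit_id,
                "bird_id": u.bird_id,
                "group": u.group,
                "n_repeats": n_trials,
                "complete": u.is_complete,
                "missing_stimuli": u.missing_stimuli(),
                "presentation_order": u.presentation_order,
                "isi_by_stimulus": u.isi_by_stimulus,
            }
        )

    (path / "spikes.csv").write_text("\n".join(spike_rows) + "\n")
    (path / "baseline.csv").write_text("\n".join(base_rows) + "\n")

    manifest = {
        "format_version": FORMAT_VERSION,
        "time_precision_s": TIME_PRECISION_S,
        "birds": session.birds(),
        "units": units_meta,
        "stimulus_ids": [s.stimulus_id for s in session.stimuli],
        "files": {
            "stimuli": "stimuli.json",
            "spikes": "spikes.csv",
            "baseline": "baseline.csv",
        },
    }
    manifest_path = path / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory.

    Spike times are sorted on load; schema violations (unknown stimuli,
    out-of-range repeat indices, spikes outside the trial window) raise
    :class:`SessionFormatError` naming the offending file.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SessionFormatError(f"no manifest.json in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    with open(path / manifest["files"]["stimuli"]) as fh:
        stimuli = [_stimulus_from_dict(d) for d in json.load(fh)]
    by_id = stimulus_index(stimuli)

    spikes_file = path / manifest["files"]["spikes"]
    spikes = pd.read_csv(spikes_file, dtype={"unit_id": str, "stimulus_id": str})
    baseline = pd.read_csv(
        path / manifest["files"]["baseline"], dtype={"unit_id": str}
    )

    if spikes.shape[0]:
        bad = ~spikes["stimulus_id"].isin(by_id)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SessionFormatError(
                f"{spikes_file}: line {row + 2}: unknown stimulus "
                f"{spikes['stimulus_id'].iloc[row]!r}"
            )
        bad = (spikes["repeat_index"] < 0) | (spikes["repeat_index"] >= N_REPEATS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SessionFormatError(
                f"{spikes_file}: line {row + 2}: repeat_index "
                f"{spikes['repeat_index'].iloc[row]} outside [0, {N_REPEATS})"
            )

    spike_groups = {
        k: g["spike_time_s"].to_numpy()
        for k, g in spikes.groupby(["unit_id", "stimulus_id", "repeat_index"], sort=False)
    }
    base_groups = {k: g["spike_time_s"].to_numpy() for k, g in baseline.groupby("unit_id")}

    units: list[UnitRecording] = []
    for meta in manifest["units"]:
        uid = meta["unit_id"]
        trials: list[Trial] = []
        for stim_id, n_rep in meta["n_repeats"].items():
            if stim_id not in by_id:
                raise SessionFormatError(
                    f"{manifest_path}: unit {uid} references unknown stimulus {stim_id!r}"
                )
            dur = by_id[stim_id].trial_duration_s
            for rep in range(int(n_rep)):
                trials.append(
                    Trial(
                        stimulus_id=stim_id,
                        repeat_index=rep,
                        spikes=spike_groups.get((uid, stim_id, rep), np.empty(0)),
                        trial_duration_s=dur,
                    )
                )
        units.append(
            UnitRecording(
                unit_id=uid,
                bird_id=meta["bird_id"],
                group=meta["group"],
                trials=trials,
                baseline=base_groups.get(uid, np.empty(0)),
                stimulus_table=stimuli,
                presentation_order=meta.get("presentation_order"),
                isi_by_stimulus=meta.get("isi_by_stimulus"),
            )
        )
    return Session(stimuli=stimuli, units=units)
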