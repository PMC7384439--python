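"""Response Strength, Selectivity Index and d' selectivity measures.

Response Strength (RS, spikes/s) for one unit x song stimulus is the
per-trial evoked rate minus that trial's own pre-stimulus rate, averaged
over the repeats:

    RS = (1/N) * sum_i (ESR_i - SSR_i)

with ESR_i the spike rate during the stimulus period of repeat i and
SSR_i the rate during its 500 ms pre-stimulus silence.  RS can be
negative for suppressed responses.

For an ordered stimulus pair (A, B):

    SI = RS_A / (RS_A + RS_B)                    (defined for RS > 0)
    d' = 2 (RS_A - RS_B) / sqrt(var_A + var_B)   (sample variances)

A unit counts as SI-selective when one response is at least twice the
other, i.e. SI <= 0.33 or SI >= 0.66.  Note the printed cut-offs are
asymmetric around the exact 2:1 boundary: 2/3 meets the upper cut-off
while the mirrored 1/3 does not fall below the lower one; the cut-offs
are applied as printed rather than "fixed".  The d' non-selectivity zone
is [-2, 2]; |d'| >= 2 counts as selective, including the zero-variance
sentinel (infinite discriminability for any mean difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .session_io import Session, UnitRecording
from .stimuli import song_label, stimulus_index

SI_LOW_CUTOFF = 0.33
SI_HIGH_CUTOFF = 0.66
DPRIME_CUTOFF = 2.0


@dataclass
class RSStats:
    """Per-trial Response Strength values for one unit x stimulus."""

    stimulus_id: str
    rs_per_trial: np.ndarray

    def __post_init__(self) -> None:
        self.rs_per_trial = np.asarray(self.rs_per_trial, dtype=float)
        if self.rs_per_trial.size == 0:
            raise ValueError(f"{self.stimulus_id}: no trials")

    @property
    def n(self) -> int:
        return int(self.rs_per_trial.size)

    @property
    def mean_rs(self) -> float:
        return float(self.rs_per_trial.mean())

    @property
    def var_rs(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(self.rs_per_trial.var(ddof=1))


@dataclass
class SelectivityResult:
    """SI, d' and selectivity calls for an ordered stimulus pair (A, B)."""

    stimulus_a: str
    stimulus_b: str
    si: Optional[float]
    dprime: float
    si_selective: bool
    dprime_selective: bool
    si_absent_reason: Optional[str] = None
    dprime_degenerate: bool = False  # both variances zero, nonzero mean diff


def response_strength(unit: UnitRecording, stimulus_id: str) -> RSStats:
    """Per-trial RS for one stimulus (evoked minus own-trial baseline)."""
    stim = stimulus_index(unit.stimulus_table)[stimulus_id]
    trials = unit.trials_for(stimulus_id)
    if not trials:
        raise ValueError(f"unit {unit.unit_id}: no trials for {stimulus_id}")
    pre = stim.pre_silence_s
    off = pre + stim.duration_s
    rs = np.array(
        [
            np.count_nonzero((t.spikes >= pre) & (t.spikes < off)) / stim.duration_s
            - np.count_nonzero(t.spikes < pre) / pre
            for t in trials
        ]
    )
    return RSStats(stimulus_id=stimulus_id, rs_per_trial=rs)


def selectivity_index(rs_a: RSStats, rs_b: RSStats) -> Optional[float]:
    """SI = RS_A / (RS_A + RS_B), defined only when both mean RS > 0.

    Negative or zero mean RS makes the ratio uninterpretable (it can
    leave [0, 1] or blow up); such pairs return None.
    """
    a, b = rs_a.mean_rs, rs_b.mean_rs
    if a <= 0 or b <= 0:
        return None
    return a / (a + b)


def dprime(rs_a: RSStats, rs_b: RSStats) -> float:
    """d' = 2 (mean_A - mean_B) / sqrt(var_A + var_B).

    When both sample variances vanish the statistic is 0 for equal means
    and an infinite sentinel (signed) otherwise.
    """
    if rs_a.n < 2 or rs_b.n < 2:
        raise ValueError("d' needs at least 2 repeats per stimulus")
    diff = rs_a.mean_rs - rs_b.mean_rs
    denom = rs_a.var_rs + rs_b.var_rs
    if denom == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return 2.0 * diff / math.sqrt(denom)


def selectivity_result(rs_a: RSStats, rs_b: RSStats) -> SelectivityResult:
    """SI and d' with their selectivity calls for an ordered pair."""
    si = selectivity_index(rs_a, rs_b)
    reason = None
    if si is None:
        reason = "non-positive mean RS"
    d = dprime(rs_a, rs_b)
    return SelectivityResult(
        stimulus_a=rs_a.stimulus_id,
        stimulus_b=rs_b.stimulus_id,
        si=si,
        dprime=d,
        si_selective=si is not None and (si <= SI_LOW_CUTOFF or si >= SI_HIGH_CUTOFF),
        dprime_selective=abs(d) >= DPRIME_CUTOFF,
        si_absent_reason=reason,
        dprime_degenerate=math.isinf(d),
    )


def song_rs(unit: UnitRecording) -> dict[str, RSStats]:
    """RSStats for every recorded song stimulus of the unit."""
    out = {}
    for stim in unit.stimulus_table:
        if stim.category != "SONG":
            continue
        if unit.trials_for(stim.stimulus_id):
            out[stim.stimulus_id] = response_strength(unit, stim.stimulus_id)
    return out


def song_comparison_panel(unit: UnitRecording) -> list[SelectivityResult]:
    """Pairwise song comparisons behind the per-song selectivity panels.

    For each forward song the panel compares it against its own reverse
    version and against the other five forward songs -- six comparisons
    per forward song for a complete unit.  Missing stimuli are skipped
    (the comparison simply does not appear), so per-unit comparison
    counts also audit completeness.
    """
    rs = song_rs(unit)
    forwards = sorted(sid for sid in rs if sid.endswith("-FOR"))
    results: list[SelectivityResult] = []
    for fid in forwards:
        rid = fid[:-4] + "-REV"
        if rid in rs:
            results.append(selectivity_result(rs[fid], rs[rid]))
        for other in forwards:
            if other != fid:
                results.append(selectivity_result(rs[fid], rs[other]))
    return results


def panel_counts(results: list[SelectivityResult]) -> pd.DataFrame:
    """Per forward song: comparisons inside/outside the d' zone [-2, 2]."""
    rows = {}
    for r in results:
        song = song_label(r.stimulus_a)
        row = rows.setdefault(song, {"n": 0, "selective": 0, "degenerate": 0})
        row["n"] += 1
        row["selective"] += int(r.dprime_selective)
        row["degenerate"] += int(r.dprime_degenerate)
    return pd.DataFrame(rows).T.astype(int)


def forward_reverse_bias(unit: UnitRecording) -> pd.DataFrame:
    """Signed distance to the FOR = REV identity line, per song.

    In the (RS_FOR, RS_REV) plane the minimum distance of a point to the
    identity line is |RS_FOR - RS_REV| / sqrt(2); the sign is positive
    when the forward response is the larger one.  Returns one row per
    song with both RS means and the signed distance.
    """
    rs = song_rs(unit)
    rows = []
    for fid in sorted(sid for sid in rs if sid.endswith("-FOR")):
        rid = fid[:-4] + "-REV"
        if rid not in rs:
            continue
        f, r = rs[fid].mean_rs, rs[rid].mean_rs
        rows.append(
            {
                "song_id": song_label(fid),
                "rs_for": f,
                "rs_rev": r,
                "signed_distance": (f - r) / math.sqrt(2.0),
            }
        )
    return pd.DataFrame(rows)


def song_rs_table(session: Session) -> pd.DataFrame:
    """Long table of song RS statistics for every unit in a session.

    One row per (unit, song stimulus): the shared input of the
    distribution summaries and the group-level inference.
    """
    rows = []
    for unit in session.units:
        for sid, stats in song_rs(unit).items():
            stim = stimulus_index(unit.stimulus_table)[sid]
            rows.append(
                (
                    unit.bird_id,
                    unit.group,
                    unit.unit_id,
                    sid,
                    song_label(sid),
                    stim.song_type,
                    stim.direction,
                    stats.mean_rs,
                    stats.var_rs,
                    stats.n,
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


def rs_distribution_summary(rs_table: pd.DataFrame) -> pd.DataFrame:
    """Group x song-type summary of the per-(unit, stimulus) mean RS.

    Means, medians and counts per group for conspecific and
    heterospecific stimuli -- the numbers behind group-level RS
    histograms and the rearing x song-type contrast.
    """
    if rs_table.empty:
        raise ValueError("empty RS table")
    out = (
        rs_table.groupby(["group", "song_type"])["mean_rs"]
        .agg(["mean", "median", "count"])
        .rename(columns={"count": "n"})
    )
    return out
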