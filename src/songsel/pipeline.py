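"""End-to-end orchestration.

``run_pipeline`` takes a scenario (simulate) or a session directory
(load), profiles every unit, computes song selectivity, runs the
clustered group inference, and writes a plain-text report bundle:
``profiles.csv``, ``selectivity.csv``, ``fr_bias.csv``, population
summary CSVs, ``inference.json``, ``report.md`` and a provenance record.
Every stage is a pure function of its inputs plus the seed, and all
intermediates are CSV/JSON so each stage can be re-run and checked in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .inference import (
    RSLongTable,
    build_long_table,
    fit_random_intercept_model,
    levene_test,
    mann_whitney_u,
    permutation_interaction_test,
)
from .selectivity import (
    forward_reverse_bias,
    song_comparison_panel,
    song_rs_table,
    rs_distribution_summary,
)
from .session_io import Session, read_session, write_session
from .simulate import ScenarioConfig, simulate_session
from .unit_profile import population_summary, unit_profile


@dataclass
class RunConfig:
    """One pipeline run: input source, output location, inference knobs."""

    out_dir: str
    scenario: Optional[ScenarioConfig] = None
    session_dir: Optional[str] = None
    seed: int = 0
    transform: str = "log"
    n_perm: int = 10_000
    alpha: float = 0.05
    baseline_stat: str = "pooled"
    write_simulated_session: bool = False

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.session_dir is None):
            raise ValueError("provide exactly one of scenario or session_dir")


def _analysis_config_dict(config: RunConfig) -> dict:
    # the output location is not part of the analysis: identical seeds and
    # inputs must give byte-identical bundles wherever they are written
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)
    return d


def _config_hash(config: RunConfig) -> str:
    d = _analysis_config_dict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _json_safe(x):
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return x if math.isfinite(x) else repr(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _profiles_frame(session: Session, baseline_stat: str):
    rows = []
    profiles = []
    for unit in session.units:
        p = unit_profile(unit, baseline_stat)
        profiles.append(p)
        rows.append(
            {
                "unit_id": p.unit_id,
                "bird_id": p.bird_id,
                "group": p.group,
                "spont_rate_hz": p.spont_rate_hz,
                "is_auditory": p.is_auditory,
                "bf_hz": p.bf_hz,
                "pattern_bf": p.pattern_bf,
                "pattern_wn": p.pattern_wn,
                "n_songs_excited": p.n_songs_excited,
                "n_missing_stimuli": len(p.missing_stimuli),
            }
        )
    return pd.DataFrame(rows), profiles


def _selectivity_frame(session: Session) -> pd.DataFrame:
    rows = []
    for unit in session.units:
        for r in song_comparison_panel(unit):
            rows.append(
                {
                    "bird_id": unit.bird_id,
                    "group": unit.group,
                    "unit_id": unit.unit_id,
                    "stimulus_a": r.stimulus_a,
                    "stimulus_b": r.stimulus_b,
                    "si": r.si,
                    "dprime": r.dprime,
                    "si_selective": r.si_selective,
                    "dprime_selective": r.dprime_selective,
                    "dprime_degenerate": r.dprime_degenerate,
                }
            )
    return pd.DataFrame(rows)


def _bias_frame(session: Session) -> pd.DataFrame:
    frames = []
    for unit in session.units:
        df = forward_reverse_bias(unit)
        if df.empty:
            continue
        df.insert(0, "unit_id", unit.unit_id)
        df.insert(0, "group", unit.group)
        df.insert(0, "bird_id", unit.bird_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["bird_id", "group", "unit_id", "song_id", "rs_for", "rs_rev", "signed_distance"]
        )
    return pd.concat(frames, ignore_index=True)


def _run_inference(rs_table: pd.DataFrame, config: RunConfig) -> dict:
    out: dict = {}
    birds_per_group = rs_table.groupby("group")["bird_id"].nunique()
    if len(birds_per_group) < 2 or birds_per_group.min() < 2:
        out["skipped"] = (
            "group inference needs at least 2 birds in each of 2 groups; "
            f"got {birds_per_group.to_dict()}"
        )
        return out

    long_table = build_long_table(rs_table, transform=config.transform)
    perm = permutation_interaction_test(
        long_table, n_perm=config.n_perm, seed=config.seed
    )
    out["permutation_interaction"] = {
        "statistic": perm.statistic,
        "p_value": perm.p_value,
        "n_permutations": perm.n_permutations,
        "exact": perm.exact,
        "significant": perm.p_value <= config.alpha,
    }

    fit = fit_random_intercept_model(long_table)
    out["random_intercept_reml"] = {
        "fixed_effects": fit.beta.to_dict(),
        "variance_components": fit.variance_components,
        "loglik_reml": fit.loglik_reml,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "transform": long_table.transform,
        "log_offset": long_table.offset,
    }

    groups = sorted(rs_table["group"].unique())
    x = rs_table.loc[rs_table["group"] == groups[0], "mean_rs"].to_numpy()
    y = rs_table.loc[rs_table["group"] == groups[1], "mean_rs"].to_numpy()
    u, p = mann_whitney_u(x, y)
    out["mann_whitney_rs_by_group"] = {"U": u, "p_value": p, "groups": groups}
    w, p = levene_test(x, y)
    out["levene_rs_by_group"] = {"W": w, "p_value": p, "groups": groups}
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        session = simulate_session(config.scenario)
        if config.write_simulated_session:
            write_session(session, out_dir / "session")
    else:
        session = read_session(config.session_dir)

    paths: dict[str, Path] = {}

    profiles_df, profiles = _profiles_frame(session, config.baseline_stat)
    paths["profiles"] = out_dir / "profiles.csv"
    profiles_df.to_csv(paths["profiles"], index=False)

    summaries = population_summary(profiles)
    for name, df in summaries.items():
        p = out_dir / f"summary_{name}.csv"
        df.to_csv(p)
        paths[f"summary_{name}"] = p

    spont = profiles_df[["group", "spont_rate_hz"]]
    edges = np.arange(0.0, 16.0, 1.0)
    hist = {
        g: np.histogram(s["spont_rate_hz"], bins=edges)[0]
        for g, s in spont.groupby("group")
    }
    spont_hist = pd.DataFrame(hist, index=[f"[{a:.0f},{b:.0f})" for a, b in zip(edges[:-1], edges[1:])])
    paths["spont_hist"] = out_dir / "spont_rate_hist.csv"
    spont_hist.to_csv(paths["spont_hist"])

    sel_df = _selectivity_frame(session)
    paths["selectivity"] = out_dir / "selectivity.csv"
    sel_df.to_csv(paths["selectivity"], index=False)

    bias_df = _bias_frame(session)
    paths["fr_bias"] = out_dir / "fr_bias.csv"
    bias_df.to_csv(paths["fr_bias"], index=False)

    rs_table = song_rs_table(session)
    paths["rs_table"] = out_dir / "rs_table.csv"
    rs_table.to_csv(paths["rs_table"], index=False)
    rs_summary = rs_distribution_summary(rs_table) if not rs_table.empty else pd.DataFrame()
    paths["rs_summary"] = out_dir / "rs_summary.csv"
    rs_summary.to_csv(paths["rs_summary"])

    inference = (
        _run_inference(rs_table, config)
        if not rs_table.empty
        else {"skipped": "no song responses"}
    )
    paths["inference"] = out_dir / "inference.json"
    with open(paths["inference"], "w") as fh:
        json.dump(_json_safe(inference), fh, indent=1, sort_keys=True)

    report = _render_report(profiles_df, summaries, sel_df, bias_df, rs_summary, inference)
    paths["report"] = out_dir / "report.md"
    paths["report"].write_text(report)

    provenance = {
        "songsel_version": __version__,
        "config": _analysis_config_dict(config),
        "config_hash": _config_hash(config),
        "n_units": len(session.units),
        "n_birds": len(session.birds()),
    }
    paths["provenance"] = out_dir / "provenance.json"
    with open(paths["provenance"], "w") as fh:
        json.dump(_json_safe(provenance), fh, indent=1, sort_keys=True)
    return paths


def _render_report(profiles_df, summaries, sel_df, bias_df, rs_summary, inference) -> str:
    lines = ["# Session analysis report", ""]
    lines += [
        f"Units: {len(profiles_df)}; auditory: {int(profiles_df['is_auditory'].sum())}",
        "",
        "## Simple-stimulus responses (% of units)",
        "",
        summaries["tone_wn_response"].round(1).to_string(),
        "",
        "## Best-frequency distribution (%)",
        "",
        summaries["bf_distribution"].round(1).to_string(),
        "",
        "## Stimulus-class combinations (%)",
        "",
        summaries["stimulus_class_combinations"].round(1).to_string(),
        "",
        "## Response-strength summary by group and song type",
        "",
        rs_summary.round(3).to_string() if len(rs_summary) else "(no song responses)",
        "",
    ]
    if not sel_df.empty:
        n_sel = int(sel_df["dprime_selective"].sum())
        lines += [
            "## Song selectivity (d')",
            "",
            f"{len(sel_df)} pairwise comparisons; {n_sel} outside the "
            f"non-selectivity zone [-2, 2].",
            "",
        ]
    if not bias_df.empty:
        frac_rev = float((bias_df["signed_distance"] < 0).mean())
        lines += [
            "## Forward/reverse bias",
            "",
            f"{len(bias_df)} song instances; {100 * frac_rev:.1f}% respond more "
            "to the reversed version.",
            "",
        ]
    lines += ["## Group inference", "", "```json", json.dumps(_json_safe(inference), indent=1, sort_keys=True), "```", ""]
    return "\n".join(lines)
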