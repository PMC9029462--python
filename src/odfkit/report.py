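"""End-to-end orchestration: generate, analyse, summarise.

``run_toolbox`` walks every film x method x replicate cell, generates the
scripted synthetic data, runs the matching analysis (simulated stopwatch
observation for the Petri dish, video profiling for the oral cavity model,
friction change-point detection for the tribometer), and aggregates the
endpoints and mean coefficients of friction into a cross-method summary
table with censoring notation (">180.0"), plus one-way ANOVA / Tukey HSD
group statistics on replicate-level values. Runs are deterministic under a
fixed seed: replicate r of any cell uses seed + r, and the summary JSON is
byte-identical between reruns of the same config.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .render import RenderConfig, render_video
from .scenarios import FILM_IDS, METHODS, build_scenario, simulate_petri_observation, synth_friction_trace
from .tribology import CofConfig, compare_groups, compute_cof, detect_friction_endpoint, mean_cof
from .types import CAP_S, EndpointResult
from .video import DisintegrationProfile, SegmentationConfig, detect_endpoint, extract_profile

__all__ = ["ToolboxConfig", "ToolboxSummary", "run_toolbox", "render_profiles"]


class ToolboxConfig(BaseModel):
    """One config drives a whole toolbox run; every knob is overridable."""

    model_config = ConfigDict(frozen=True)

    films: tuple[str, ...] = FILM_IDS
    methods: tuple[str, ...] = METHODS
    n_replicates: int = Field(3, ge=1)
    seed: int = 0
    cap_s: float = Field(CAP_S, gt=0)
    persistence_frames: int = Field(5, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    render: RenderConfig = RenderConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    cof: CofConfig = CofConfig()
    #: per-cell scenario overrides keyed "FILM:method", e.g. {"P1:ocm": {"duration_s": 40}}
    scenario_overrides: dict[str, dict] = Field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ToolboxSummary:
    """Aggregated cross-method results with provenance."""

    cells: dict
    cof: dict
    stats: dict
    provenance: dict
    profiles: dict = field(default_factory=dict, repr=False)

    def table(self) -> str:
        """Render the endpoint summary as a plain-text cross-method table."""
        methods = sorted({m for (_, m) in self.cells})
        films = sorted({f for (f, _) in self.cells})
        lines = ["film\t" + "\t".join(methods)]
        for f in films:
            row = [f]
            for m in methods:
                cell = self.cells[(f, m)]
                row.append(cell.get("rendered", "-"))
            lines.append("\t".join(row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cells": {f"{f}:{m}": v for (f, m), v in sorted(self.cells.items())},
            "cof": self.cof,
            "stats": self.stats,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _aggregate_cell(results: list[EndpointResult], cap_s: float) -> dict:
    times = [r.time_s for r in results if not r.censored]
    n_cens = sum(r.censored for r in results)
    cell: dict = {
        "n": len(results),
        "n_censored": n_cens,
        "times_s": times,
        "source": results[0].source,
    }
    if n_cens == len(results):
        cell.update(censored=True, mean_s=None, sd_s=None, rendered=f">{cap_s:.1f}")
    else:
        mean = float(np.mean(times))
        cell["censored"] = False
        cell["mean_s"] = mean
        if len(times) >= 2:
            cell["sd_s"] = float(np.std(times, ddof=1))
            cell["rendered"] = f"{mean:.1f} ± {cell['sd_s']:.1f}"
        else:
            cell["sd_s"] = None
            cell["flag"] = "sd unavailable (n < 2)"
            cell["rendered"] = f"{mean:.1f}"
        if n_cens:
            cell["flag"] = f"{n_cens} replicate(s) censored; mean over observed only"
    return cell


def _run_cell(
    film: str, method: str, rep_seed: int, config: ToolboxConfig
) -> tuple[EndpointResult, Optional[float], Optional[DisintegrationProfile]]:
    overrides = dict(config.scenario_overrides.get(f"{film}:{method}", {}))
    overrides.setdefault("seed", rep_seed)
    scenario = build_scenario(film, method, overrides)
    if method == "petri":
        (res,) = simulate_petri_observation(scenario, 1, rep_seed, cap_s=config.cap_s)
        return res, None, None
    if method == "ocm":
        seq = render_video(scenario, rep_seed, config.render)
        profile = extract_profile(seq, config.segmentation)
        res = detect_endpoint(profile, config.persistence_frames, config.cap_s)
        return res, None, profile
    # btm: friction signature is the endpoint detector; mean CoF summarises feel
    trace = synth_friction_trace(
        scenario,
        rep_seed,
        sample_rate_hz=100.0,
        freq_hz=config.cof.freq_hz,
    )
    series = compute_cof(trace, config.cof)
    res = detect_friction_endpoint(series, cap_s=config.cap_s)
    return res, mean_cof(series), None


def run_toolbox(config: Optional[ToolboxConfig] = None) -> ToolboxSummary:
    """Run every configured film x method cell and aggregate the results.

    A failure in one cell is recorded on that cell (with the stage's error
    message) and the run continues. Censored endpoints never enter means or
    group statistics.
    """
    config = config or ToolboxConfig()
    cells: dict = {}
    cof_reps: dict[str, list[float]] = {}
    profiles: dict = {}
    for film in config.films:
        for method in config.methods:
            results: list[EndpointResult] = []
            try:
                for rep in range(config.n_replicates):
                    rep_seed = config.seed + rep
                    res, mu, profile = _run_cell(film, method, rep_seed, config)
                    results.append(res)
                    if mu is not None:
                        cof_reps.setdefault(film, []).append(mu)
                    if profile is not None:
                        profiles.setdefault((film, method), []).append(profile)
                cells[(film, method)] = _aggregate_cell(results, config.cap_s)
            except Exception as exc:  # cell fails, run continues
                cells[(film, method)] = {"error": f"{type(exc).__name__}: {exc}"}

    cof_summary = {
        film: {
            "replicates": [float(v) for v in vals],
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else None,
        }
        for film, vals in sorted(cof_reps.items())
    }

    stats: dict = {}
    usable_cof = {f: v for f, v in cof_reps.items() if len(v) >= 2}
    if len(usable_cof) >= 2:
        gs = compare_groups(usable_cof, config.alpha)
        stats["mean_cof"] = {
            "anova_F": gs.anova_F if math.isfinite(gs.anova_F) else None,
            "anova_p": gs.anova_p,
            "tukey_p": {f"{a}|{b}": p for (a, b), p in gs.tukey_p.items()},
        }
    # endpoint ANOVA per method over films with >= 2 observed replicates
    for method in config.methods:
        groups = {}
        for film in config.films:
            cell = cells.get((film, method), {})
            times = cell.get("times_s") or []
            if len(times) >= 2:
                groups[film] = times
        if len(groups) >= 2:
            gs = compare_groups(groups, config.alpha)
            stats[f"endpoint_{method}"] = {
                "anova_F": gs.anova_F if math.isfinite(gs.anova_F) else None,
                "anova_p": gs.anova_p,
                "tukey_p": {f"{a}|{b}": p for (a, b), p in gs.tukey_p.items()},
            }

    provenance = {
        "seed": config.seed,
        "replicate_seeds": list(range(config.seed, config.seed + config.n_replicates)),
        "config_hash": config.config_hash(),
        "package": "odfkit",
    }
    return ToolboxSummary(cells=cells, cof=cof_summary, stats=stats, provenance=provenance, profiles=profiles)


def render_profiles(profiles: dict, out_dir, cof_by_film: Optional[dict] = None) -> dict:
    """Write mean ± sd disintegration-profile plots (and CoF-time plots).

    ``profiles`` maps ``(film_id, method)`` (or plain film id) to a list of
    replicate :class:`DisintegrationProfile`. Returns, per plot, the series
    actually drawn (time, mean, sd and output path) so callers can verify
    the plotted data without reading images back.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not profiles:
        raise ValueError("empty profile list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drawn: dict = {}
    for key, reps in profiles.items():
        if not reps:
            raise ValueError(f"no replicate profiles for {key}")
        name = key if isinstance(key, str) else "_".join(str(k) for k in key)
        n = min(len(p) for p in reps)
        t = reps[0].t_s[:n]
        stack = np.vstack([p.area_fraction[:n] for p in reps])
        mean, sd = stack.mean(axis=0), stack.std(axis=0)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(t, mean, lw=1.2, color="crimson", label="mean area fraction")
        ax.fill_between(t, mean - sd, mean + sd, alpha=0.25, color="crimson", label="± sd")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("area fraction")
        ax.set_title(name)
        ax.legend(frameon=False, fontsize=8)
        path = out / f"profile_{name}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        drawn[name] = {"t_s": t, "mean": mean, "sd": sd, "path": str(path)}
    if cof_by_film:
        for film, series in cof_by_film.items():
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.plot(series.t_mid_s, series.mu, lw=1.0, color="navy")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("coefficient of friction")
            ax.set_title(f"{film} (BTM)")
            path = out / f"cof_{film}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            drawn[f"cof_{film}"] = {
                "t_s": series.t_mid_s,
                "mean": series.mu,
                "sd": None,
                "path": str(path),
            }
    return drawn
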