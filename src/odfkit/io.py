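"""Plain-text readers and writers for the toolbox's tabular formats.

Force traces and flow curves travel as headered CSV; disintegration
profiles as CSV; endpoints and scenarios as JSON; frames as a PNG
directory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .rheology import FlowCurve
from .scenarios import FilmScenario
from .tribology import FrictionTrace
from .video import DisintegrationProfile

TRACE_COLUMNS = ["time_s", "ff1_N", "ff2_N", "fn_N", "pos_mm"]
FLOW_COLUMNS = ["shear_rate_1_per_s", "viscosity_Pa_s"]
PROFILE_COLUMNS = ["t_s", "area_px", "area_fraction", "perimeter_px", "n_fragments"]


def write_trace_csv(trace: FrictionTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.t_s,
            "ff1_N": trace.ff1_N,
            "ff2_N": trace.ff2_N,
            "fn_N": trace.fn_N,
            "pos_mm": trace.pos_mm if trace.pos_mm is not None else np.nan,
        }
    )
    df.to_csv(path, index=False)


def read_trace_csv(path) -> FrictionTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    pos = df["pos_mm"].to_numpy() if "pos_mm" in df.columns else None
    if pos is not None and np.all(np.isnan(pos)):
        pos = None
    return FrictionTrace(
        t_s=df["time_s"].to_numpy(),
        ff1_N=df["ff1_N"].to_numpy(),
        ff2_N=df["ff2_N"].to_numpy(),
        fn_N=df["fn_N"].to_numpy(),
        pos_mm=pos,
    )


def write_flow_csv(curve: FlowCurve, path) -> None:
    pd.DataFrame(
        {
            "shear_rate_1_per_s": curve.shear_rate_1_per_s,
            "viscosity_Pa_s": curve.viscosity_Pa_s,
        }
    ).to_csv(path, index=False)


def read_flow_csv(path) -> FlowCurve:
    df = pd.read_csv(path)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flow-curve CSV missing columns: {missing}")
    return FlowCurve(
        shear_rate_1_per_s=df["shear_rate_1_per_s"].to_numpy(),
        viscosity_Pa_s=df["viscosity_Pa_s"].to_numpy(),
    )


def write_profile_csv(profile: DisintegrationProfile, path) -> None:
    pd.DataFrame(
        {
            "t_s": profile.t_s,
            "area_px": profile.area_px,
            "area_fraction": profile.area_fraction,
            "perimeter_px": profile.perimeter_px,
            "n_fragments": profile.n_fragments,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path) -> DisintegrationProfile:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    area = df["area_px"].to_numpy(dtype=float)
    return DisintegrationProfile(
        t_s=df["t_s"].to_numpy(dtype=float),
        area_px=area,
        perimeter_px=df["perimeter_px"].to_numpy(dtype=float),
        n_fragments=df["n_fragments"].to_numpy(dtype=int),
        largest_fragment_area_px=area.copy(),
        area_fraction=df["area_fraction"].to_numpy(dtype=float),
    )


def write_scenario_json(scenario: FilmScenario, path) -> None:
    Path(path).write_text(scenario.model_dump_json(indent=2))


def read_scenario_json(path) -> FilmScenario:
    return FilmScenario.model_validate(json.loads(Path(path).read_text()))


def write_frames(frames, out_dir, stride: int = 1, masks: bool = False) -> list[Path]:
    """Write a frame sequence as numbered PNGs (optionally with GT masks)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(0, len(frames), stride):
        p = out / f"frame_{i:06d}.png"
        iio.imwrite(p, np.asarray(frames[i]))
        paths.append(p)
        if masks and hasattr(frames, "mask"):
            iio.imwrite(out / f"mask_{i:06d}.png", frames.mask(i).astype(np.uint8) * 255)
    return paths


def read_frames(frame_dir, pattern: str = "frame_*.png") -> list[np.ndarray]:
    paths = sorted(Path(frame_dir).glob(pattern))
    if not paths:
        raise ValueError(f"no frames matching {pattern!r} in {frame_dir}")
    return [iio.imread(p) for p in paths]
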