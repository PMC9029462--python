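"""Coefficient-of-friction analysis for reciprocating soft-tribometer traces.

The BioTribometer slides an acrylic "palate" over a silicone "tongue" with
the film and simulated salivary fluid (SSF) in between, at 1 Hz over a
7.5 mm stroke under a 1 N load, logging two in-plane friction-force channels
and a normal-force channel at 100 Hz. This module turns those traces into
per-stroke coefficient-of-friction (CoF) series, summarises mean CoF, and
detects the disintegration endpoint from the friction signature: the films
show either a rapid decline of CoF immediately before disintegration or a
fluctuating phase, but in both cases friction settles onto a terminal
plateau once the film has broken down — so the endpoint is reported as the
onset of the terminal plateau of a piecewise-constant fit selected by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .types import CAP_S, EndpointResult

__all__ = [
    "FrictionTrace",
    "CoFSeries",
    "GroupStats",
    "CofConfig",
    "compute_cof",
    "mean_cof",
    "detect_friction_endpoint",
    "compare_groups",
    "ssf_flow_rate_ml_per_min",
]


@dataclass
class FrictionTrace:
    """Raw force channels from one BTM run (nominally 100 Hz).

    ``ff1_N``/``ff2_N`` are the two orthogonal in-plane friction channels,
    ``fn_N`` the applied normal load (~1 N) and ``pos_mm`` the optional
    reciprocating stage position. ``meta`` carries provenance such as the
    SSF dosing schedule; it does not enter the CoF computation.
    """

    t_s: np.ndarray
    ff1_N: np.ndarray
    ff2_N: np.ndarray
    fn_N: np.ndarray
    pos_mm: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        for name in ("ff1_N", "ff2_N", "fn_N"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t_s.shape:
                raise ValueError(f"channel {name} length differs from t_s")
            setattr(self, name, arr)
        if self.pos_mm is not None:
            self.pos_mm = np.asarray(self.pos_mm, dtype=float)
            if self.pos_mm.shape != self.t_s.shape:
                raise ValueError("pos_mm length differs from t_s")
        if self.t_s.size >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("t_s must be strictly increasing")


@dataclass
class CoFSeries:
    """Per-stroke coefficient of friction. Invalid strokes carry mu = NaN."""

    stroke_index: np.ndarray
    t_start_s: np.ndarray
    t_mid_s: np.ndarray
    mu: np.ndarray
    n_valid_samples: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.mu)


@dataclass(frozen=True)
class GroupStats:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    groups: tuple[str, ...]
    means: dict
    sds: dict
    anova_F: float
    anova_p: float
    tukey_p: dict
    alpha: float = 0.05


class CofConfig(BaseModel):
    """Settings for stroke segmentation and sample masking."""

    model_config = ConfigDict(frozen=True)

    freq_hz: float = Field(1.0, gt=0, description="reciprocation frequency")
    fn_floor_n: float = Field(0.1, ge=0, description="drop samples below this normal force")
    central_frac: float = Field(
        0.6, gt=0, le=1, description="central fraction of travel kept (turnaround masking)"
    )
    min_samples_per_stroke: int = Field(5, ge=1)


def compute_cof(trace: FrictionTrace, config: CofConfig | None = None) -> CoFSeries:
    """Per-stroke coefficient of friction from a force trace.

    Sample-level mu is the Euclidean resultant of the two friction channels
    divided by the normal force; samples with normal force below the floor
    are excluded, as are samples near the stroke turnarounds where the
    sliding speed vanishes and instantaneous mu is ill-defined (only the
    central ``central_frac`` of each traversal is kept). One stroke = one
    full reciprocation cycle. Strokes with too few valid samples are flagged
    invalid (mu = NaN), never silently dropped.
    """
    config = config or CofConfig()
    if trace.t_s.size == 0:
        raise ValueError("empty trace")
    mu_samp = np.hypot(trace.ff1_N, trace.ff2_N) / np.where(trace.fn_N != 0, trace.fn_N, np.nan)
    ok = np.isfinite(mu_samp) & (trace.fn_N >= config.fn_floor_n)

    if trace.pos_mm is not None and np.ptp(trace.pos_mm) > 0:
        pos = trace.pos_mm
        mid = 0.5 * (pos.min() + pos.max())
        half = 0.5 * np.ptp(pos)
        ok &= np.abs(pos - mid) <= config.central_frac * half
    else:
        phase = (trace.t_s * config.freq_hz) % 0.5  # distance into each traversal
        edge = 0.5 * (1.0 - config.central_frac) / 2.0
        ok &= (phase >= edge) & (phase <= 0.5 - edge)

    t0 = trace.t_s[0]
    stroke = np.floor((trace.t_s - t0) * config.freq_hz).astype(int)
    n_strokes = int(stroke.max()) + 1

    mu = np.full(n_strokes, np.nan)
    n_valid = np.zeros(n_strokes, dtype=int)
    counts = np.bincount(stroke[ok], minlength=n_strokes)
    sums = np.bincount(stroke[ok], weights=mu_samp[ok], minlength=n_strokes)
    good = counts >= config.min_samples_per_stroke
    mu[good] = sums[good] / counts[good]
    n_valid[:] = counts

    if not np.any(good):
        raise ValueError("no valid strokes: all samples excluded by masking or force floor")

    idx = np.arange(n_strokes)
    period = 1.0 / config.freq_hz
    return CoFSeries(
        stroke_index=idx,
        t_start_s=t0 + idx * period,
        t_mid_s=t0 + (idx + 0.5) * period,
        mu=mu,
        n_valid_samples=n_valid,
    )


def mean_cof(series: CoFSeries, until_s: Optional[float] = None) -> float:
    """Unweighted mean of valid per-stroke mu up to ``until_s`` (default all)."""
    sel = series.valid
    if until_s is not None:
        sel = sel & (series.t_mid_s <= until_s)
    if not np.any(sel):
        raise ValueError("no valid strokes in the requested window")
    return float(np.mean(series.mu[sel]))


# ---------------------------------------------------------------------------
# Change-point endpoint detection


def _segment_costs(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    return s, s2


def _sse(s: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    """Sum of squared residuals of y[i:j] about its mean."""
    n = j - i
    tot = s[j] - s[i]
    return float(s2[j] - s2[i] - tot * tot / n)


def fit_piecewise_constant(y: np.ndarray, k: int) -> tuple[list[int], float]:
    """Best least-squares piecewise-constant fit with ``k`` change-points.

    Exhaustive over all placements (k <= 2), exact. Returns the change-point
    indices (segment start positions) and the total SSE.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    s, s2 = _segment_costs(y)
    if k == 0:
        return [], _sse(s, s2, 0, n)
    if k == 1:
        best = (math.inf, [0])
        for c in range(1, n):
            sse = _sse(s, s2, 0, c) + _sse(s, s2, c, n)
            if sse < best[0]:
                best = (sse, [c])
        return best[1], best[0]
    if k == 2:
        # precompute tail costs for every second cut
        best = (math.inf, [0, 0])
        left = np.empty(n)
        for c1 in range(1, n - 1):
            left_cost = _sse(s, s2, 0, c1)
            for c2 in range(c1 + 1, n):
                sse = left_cost + _sse(s, s2, c1, c2) + _sse(s, s2, c2, n)
                if sse < best[0]:
                    best = (sse, [c1, c2])
        return best[1], best[0]
    raise ValueError("k must be 0, 1 or 2")


def detect_friction_endpoint(
    series: CoFSeries,
    *,
    cap_s: float = CAP_S,
    max_changepoints: int = 2,
    min_valid_strokes: int = 10,
) -> EndpointResult:
    """Disintegration endpoint from the friction signature.

    Fits piecewise-constant models with 0..``max_changepoints`` change-points
    to the valid per-stroke mu series, selects the model by BIC, and reports
    the start time of the terminal plateau segment. If the constant
    (0-change-point) model wins, no disintegration signature is present and
    the result is censored. Handles both the decline-then-plateau and
    fluctuate-then-plateau shapes, since only the terminal plateau onset is
    reported.
    """
    sel = series.valid
    y = series.mu[sel]
    t_start = series.t_start_s[sel]
    if y.size < min_valid_strokes:
        raise ValueError(
            f"need at least {min_valid_strokes} valid strokes, got {y.size}"
        )
    n = y.size
    best_k, best_bic, best_cps = 0, math.inf, []
    for k in range(0, max_changepoints + 1):
        cps, sse = fit_piecewise_constant(y, k)
        bic = n * math.log((sse + 1e-12) / n) + (2 * k + 1) * math.log(n)
        if bic < best_bic:
            best_k, best_bic, best_cps = k, bic, cps
    if best_k == 0:
        return EndpointResult(None, censored=True, source="friction_changepoint", cap_s=cap_s)
    t_end = float(t_start[best_cps[-1]])
    detail = {"n_changepoints": best_k, "changepoint_strokes": [int(c) for c in best_cps]}
    if t_end > cap_s:
        return EndpointResult(None, censored=True, source="friction_changepoint", cap_s=cap_s)
    return EndpointResult(
        t_end, censored=False, source="friction_changepoint", cap_s=cap_s, detail=detail
    )


# ---------------------------------------------------------------------------
# Group statistics


def compare_groups(
    replicate_means: dict[str, Sequence[float]], alpha: float = 0.05
) -> GroupStats:
    """One-way ANOVA with Tukey HSD across per-film replicate summaries."""
    names = tuple(replicate_means)
    groups = [np.asarray(replicate_means[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    tukey_p: dict = {}
    if ssb == 0.0:
        F, p = 0.0, 1.0
    elif ssw == 0.0:
        # degenerate: identical replicates within every group
        F, p = math.inf, 0.0
    else:
        F, p = stats.f_oneway(*groups)
        F, p = float(F), float(p)
    if ssw == 0.0:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                same = groups[i].mean() == groups[j].mean()
                tukey_p[(names[i], names[j])] = 1.0 if same else 0.0
    else:
        tukey = stats.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                tukey_p[(names[i], names[j])] = float(tukey.pvalue[i, j])
    return GroupStats(
        groups=names,
        means={g: float(np.mean(v)) for g, v in zip(names, groups)},
        sds={g: float(np.std(v, ddof=1)) for g, v in zip(names, groups)},
        anova_F=F,
        anova_p=min(max(p, 0.0), 1.0),
        tukey_p=tukey_p,
        alpha=alpha,
    )


def ssf_flow_rate_ml_per_min(
    volume_ul: float = 100.0, strokes_per_dose: int = 4, freq_hz: float = 1.0
) -> float:
    """Equivalent SSF flow rate for manual dosing (default 100 uL / 4 strokes
    at 1 Hz, i.e. 1.5 mL/min)."""
    if volume_ul <= 0 or strokes_per_dose < 1 or freq_hz <= 0:
        raise ValueError("dosing parameters must be positive")
    dose_interval_s = strokes_per_dose / freq_hz
    return (volume_ul / 1000.0) / dose_interval_s * 60.0
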