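"""Ground-truth-scripted synthetic scenarios for film disintegration tests.

The physical study characterised four single-polymer orodispersible films
(C1/C2: sodium carboxymethylcellulose of 395/725 kDa; P1/P2: polyvinyl
alcohol of 39/197 kDa) with three bench methods: a shaken Petri dish with a
stopwatch endpoint, an oral cavity model (OCM) filmed from above at 30 fps,
and a reciprocating soft bio-tribometer (BTM) logging friction at 100 Hz.
No raw videos or force traces are public, so this module scripts synthetic
inputs whose ground truth is known exactly: each :class:`FilmScenario`
carries the film's identity, the method, a schedule of geometric
disintegration events and (for the BTM) a friction signature. Downstream
analysis stages are then testable by parameter recovery.

Scenario parameters — endpoint means and spreads, event schedules, friction
signatures — live in one packaged JSON file (``data/scenarios.json``), not in
code.
"""

from __future__ import annotations

import json
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Any, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .rheology import FlowCurve
from .tribology import FrictionTrace
from .types import CAP_S, EndpointResult

__all__ = [
    "FilmSpec",
    "DisintegrationEvent",
    "CofSignature",
    "FilmScenario",
    "FILM_IDS",
    "METHODS",
    "build_scenario",
    "packaged_params",
    "packaged_flow_params",
    "mu_profile",
    "synth_friction_trace",
    "synth_flow_curve",
    "simulate_petri_observation",
]

FILM_IDS = ("C1", "C2", "P1", "P2")
METHODS = ("petri", "ocm", "btm")

_EVENT_KINDS = ("shrink", "tear", "detach", "coalesce", "swell")


@lru_cache(maxsize=1)
def packaged_params() -> dict:
    """The packaged scenario parameter table (read-only)."""
    with resources.files("odfkit.data").joinpath("scenarios.json").open() as fh:
        return json.load(fh)


class FilmSpec(BaseModel):
    """Identity and nominal geometry of one printed film."""

    model_config = ConfigDict(frozen=True)

    film_id: Literal["C1", "C2", "P1", "P2"]
    polymer: Literal["CMC", "PVA"]
    mw_kda: float = Field(gt=0, description="polymer molecular weight, kDa")
    conc_pct_wv: float = Field(gt=0, description="stock solution concentration, % w/v")
    width_mm: float = Field(30.0, gt=0)
    height_mm: float = Field(20.0, gt=0)
    thickness_um: float = Field(gt=0)


class DisintegrationEvent(BaseModel):
    """One scripted geometric event in a film's disintegration history.

    ``kind`` is one of shrink (gradual area loss), tear (a cut opens,
    optionally bridged after ``split_s`` so the film reads as one object),
    detach (a fragment separates and drifts off the tongue), coalesce
    (a prior tear closes again; ``target_onset_s`` names it) and swell
    (slow dilation, the palate-adhering CMC behaviour).
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["shrink", "tear", "detach", "coalesce", "swell"]
    onset_s: float = Field(ge=0)
    params: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_params(self) -> "DisintegrationEvent":
        p = self.params
        if self.kind == "detach":
            f = p.get("area_frac", 0.1)
            if not 0 < f < 1:
                raise ValueError("detach area_frac must lie in (0, 1)")
        if self.kind == "tear" and p.get("region", "vertical") == "corner":
            f = p.get("area_frac", 0.05)
            if not 0 < f < 0.5:
                raise ValueError("corner tear area_frac must lie in (0, 0.5)")
        if self.kind == "coalesce" and "target_onset_s" not in p:
            raise ValueError("coalesce event requires params.target_onset_s")
        return self


class CofSignature(BaseModel):
    """Scripted coefficient-of-friction trajectory for a BTM run.

    ``decline_plateau`` holds ``mu_initial`` until a short rapid decline of
    ``decline_s`` seconds ending at ``transition_s``, then sits at
    ``mu_plateau`` (the CMC-film signature). ``fluctuate_plateau`` oscillates
    about ``mu_initial`` with amplitude ``fluctuation_amp`` before dropping to
    the plateau at ``transition_s`` (the PVA-film signature). The transition
    time is the scripted disintegration endpoint.
    """

    model_config = ConfigDict(frozen=True)

    shape: Literal["decline_plateau", "fluctuate_plateau"]
    mu_initial: float = Field(gt=0, lt=1.5)
    mu_plateau: float = Field(gt=0, lt=1.5)
    transition_s: float = Field(gt=0)
    decline_s: float = Field(2.0, gt=0)
    fluctuation_amp: float = Field(0.0, ge=0)
    fluctuation_period_s: float = Field(10.0, gt=0)
    noise_sd: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check_shape(self) -> "CofSignature":
        if self.shape == "decline_plateau" and not self.mu_plateau < self.mu_initial:
            raise ValueError("decline_plateau requires mu_plateau < mu_initial")
        return self


class FilmScenario(BaseModel):
    """Complete ground-truth script for one film under one method."""

    model_config = ConfigDict(frozen=True)

    film: FilmSpec
    method: Literal["petri", "ocm", "btm"]
    duration_s: float = Field(gt=0, le=CAP_S)
    events: tuple[DisintegrationEvent, ...] = ()
    true_endpoint_s: Optional[float] = Field(None, gt=0)
    censored: bool = False
    cof_signature: Optional[CofSignature] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FilmScenario":
        onsets = [e.onset_s for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be ordered by onset time")
        if any(o >= self.duration_s for o in onsets if o > 0):
            raise ValueError("event onset must precede the scenario duration")
        if self.censored:
            if self.true_endpoint_s is not None:
                raise ValueError("censored scenario must not carry an endpoint")
        else:
            if self.true_endpoint_s is None:
                raise ValueError("non-censored scenario requires true_endpoint_s")
            if self.true_endpoint_s > self.duration_s:
                raise ValueError("true_endpoint_s must not exceed duration_s")
        if (self.cof_signature is not None) != (self.method == "btm"):
            raise ValueError("cof_signature present iff method == 'btm'")
        if self.cof_signature is not None and self.cof_signature.transition_s >= self.duration_s:
            raise ValueError("CoF transition must precede the scenario duration")
        # a coalesce event must name a prior tear/detach by its onset
        openers = {e.onset_s for e in self.events if e.kind in ("tear", "detach")}
        for e in self.events:
            if e.kind == "coalesce":
                tgt = e.params["target_onset_s"]
                if tgt not in openers or tgt >= e.onset_s:
                    raise ValueError(
                        "coalesce must reference a prior tear/detach onset"
                    )
        return self


def build_scenario(
    film_id: str, method: str, overrides: Optional[dict[str, Any]] = None
) -> FilmScenario:
    """Build the packaged scenario for one film × method cell.

    The scripted endpoint equals the packaged mean disintegration time for
    that cell; cells where the film never disintegrated within the 180 s
    Pharmacopoeial cap are censored. ``overrides`` (e.g. ``{"duration_s": 40,
    "seed": 3}``) are applied on top of the packaged values and re-validated.
    """
    if film_id not in FILM_IDS:
        raise ValueError(f"unknown film_id {film_id!r}; expected one of {FILM_IDS}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    p = packaged_params()
    cell = p["endpoints"][method][film_id]
    data: dict[str, Any] = {
        "film": {"film_id": film_id, **p["films"][film_id]},
        "method": method,
        "duration_s": p["durations_s"][method][film_id],
        "events": p["events"][method][film_id],
        "censored": bool(cell.get("censored", False)),
        "true_endpoint_s": cell.get("mean_s"),
    }
    if method == "btm":
        data["cof_signature"] = p["cof_signatures"][film_id]
    if overrides:
        data.update(overrides)
        if (
            "duration_s" in overrides
            and "events" not in overrides
            and float(overrides["duration_s"]) > 0
        ):
            # truncating the observation window drops out-of-window events
            dur = float(overrides["duration_s"])
            kept = [e for e in data["events"] if e["onset_s"] < dur]
            kept = [
                e
                for e in kept
                if e["kind"] != "coalesce"
                or any(
                    o["kind"] in ("tear", "detach") and o["onset_s"] == e["params"]["target_onset_s"]
                    for o in kept
                )
            ]
            data["events"] = kept
            if data.get("true_endpoint_s") is not None and data["true_endpoint_s"] > dur:
                raise ValueError(
                    f"duration override {dur} s truncates before the scripted "
                    f"endpoint at {data['true_endpoint_s']} s; extend the window"
                )
    return FilmScenario.model_validate(data)


# ---------------------------------------------------------------------------
# Friction traces


def mu_profile(signature: CofSignature, t: np.ndarray) -> np.ndarray:
    """Noise-free scripted coefficient of friction at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    T, d = signature.transition_s, signature.decline_s
    if signature.shape == "decline_plateau":
        pre = np.full_like(t, signature.mu_initial)
        # rapid linear decline over the last decline_s before the transition
        ramp = (t - (T - d)) / d
        mu = pre + np.clip(ramp, 0.0, 1.0) * (signature.mu_plateau - signature.mu_initial)
    else:  # fluctuate_plateau: decrease-increase-decrease about mu_initial
        osc = signature.mu_initial - signature.fluctuation_amp * np.sin(
            2 * np.pi * t / signature.fluctuation_period_s
        )
        mu = np.where(t < T, osc, signature.mu_plateau)
    return np.clip(mu, 1e-3, None)


def synth_friction_trace(
    scenario: FilmScenario,
    seed: int,
    *,
    sample_rate_hz: float = 100.0,
    freq_hz: float = 1.0,
    stroke_mm: float = 7.5,
    load_n: float = 1.0,
    fn_noise_sd: float = 0.02,
) -> FrictionTrace:
    """Synthesise a BTM force trace following the scenario's CoF signature.

    Channels mirror the rig: a triangular stage position (constant-speed
    reciprocation over ``stroke_mm`` at ``freq_hz``), a ~``load_n`` normal
    force, and two in-plane friction channels whose Euclidean resultant
    equals mu(t) x normal force with sign following the sliding direction.
    Gaussian noise of the signature's ``noise_sd`` is applied to mu; the
    normal channel carries independent sensor noise. Deterministic in
    ``(scenario, seed)``.
    """
    if scenario.method != "btm":
        raise ValueError("friction traces are only defined for method='btm'")
    sig = scenario.cof_signature
    assert sig is not None
    n = int(round(scenario.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    rng = np.random.default_rng([int(seed), 0x5F1C])

    phase = (t * freq_hz) % 1.0
    tri = 1.0 - np.abs(2.0 * phase - 1.0)  # 0 -> 1 -> 0 per cycle
    pos = stroke_mm * tri
    direction = np.where(phase < 0.5, 1.0, -1.0)

    mu = mu_profile(sig, t)
    if sig.noise_sd > 0:
        mu = mu + sig.noise_sd * rng.standard_normal(n)
    mu = np.clip(mu, 0.0, None)
    fn = load_n + fn_noise_sd * rng.standard_normal(n)
    fn = np.clip(fn, 0.05, None)

    theta = np.deg2rad(5.0)  # fixed in-plane mounting angle of the resultant
    ff_res = mu * fn * direction
    meta = {
        "film_id": scenario.film.film_id,
        "freq_hz": freq_hz,
        "stroke_mm": stroke_mm,
        "load_n": load_n,
        "sample_rate_hz": sample_rate_hz,
        "ssf_volume_ul": 100.0,
        "ssf_strokes_per_dose": 4,
        "seed": int(seed),
    }
    return FrictionTrace(
        t_s=t,
        ff1_N=ff_res * np.cos(theta),
        ff2_N=ff_res * np.sin(theta),
        fn_N=fn,
        pos_mm=pos,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Flow curves


def packaged_flow_params(film_id: str) -> dict:
    """Stand-in flow-curve model parameters for one film's stock solution."""
    if film_id not in FILM_IDS:
        raise ValueError(f"unknown film_id {film_id!r}")
    d = dict(packaged_params()["rheology"][film_id])
    return d


def synth_flow_curve(
    model_params: dict[str, Any],
    seed: int,
    *,
    n_points: int = 30,
    shear_min: float = 0.01,
    shear_max: float = 100.0,
    noise_sd: float = 0.0,
) -> FlowCurve:
    """Synthesise a rotational-rheometry flow curve.

    Emulates the bench protocol: ``n_points`` shear rates ascending
    logarithmically over [``shear_min``, ``shear_max``] 1/s (default 30 points
    on [0.01, 100]), with viscosity from a power-law
    (eta = K * gamma_dot**(n-1)) or Cross model plus multiplicative
    log-normal noise of sigma ``noise_sd``.
    """
    model = model_params.get("model", "power_law")
    shear = np.logspace(np.log10(shear_min), np.log10(shear_max), n_points)
    shear[0], shear[-1] = shear_min, shear_max  # pin the protocol endpoints
    if model == "power_law":
        K, n_idx = float(model_params["K"]), float(model_params["n"])
        if K <= 0:
            raise ValueError("power-law consistency K must be positive")
        eta = K * shear ** (n_idx - 1.0)
    elif model == "cross":
        eta0, eta_inf = float(model_params["eta0"]), float(model_params["eta_inf"])
        lam, m = float(model_params["lam"]), float(model_params["m"])
        if not eta_inf < eta0:
            raise ValueError("Cross model requires eta_inf < eta0")
        if lam <= 0 or m <= 0:
            raise ValueError("Cross parameters lam and m must be positive")
        eta = eta_inf + (eta0 - eta_inf) / (1.0 + (lam * shear) ** m)
    else:
        raise ValueError(f"unknown flow-curve model {model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng([int(seed), 0xF10C])
        eta = eta * np.exp(noise_sd * rng.standard_normal(n_points))
    return FlowCurve(shear_rate_1_per_s=shear, viscosity_Pa_s=eta)


# ---------------------------------------------------------------------------
# Petri-dish observations


def simulate_petri_observation(
    scenario: FilmScenario,
    n_replicates: int,
    seed: int,
    *,
    latency_sd_s: Optional[float] = None,
    cap_s: float = CAP_S,
) -> list[EndpointResult]:
    """Simulate stopwatch observations of Petri-dish disintegration.

    Each replicate observes the scripted endpoint plus a zero-mean truncated
    normal operator latency (truncated at ±2 sd; sd defaults to the packaged
    replicate spread for the film). Censored scenarios always yield the
    censored marker at ``cap_s``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if latency_sd_s is None:
        cell = packaged_params()["endpoints"]["petri"][scenario.film.film_id]
        latency_sd_s = float(cell.get("sd_s", 0.0))
    results: list[EndpointResult] = []
    rng = np.random.default_rng([int(seed), 0x9E72])
    for _ in range(n_replicates):
        if scenario.censored:
            results.append(
                EndpointResult(None, censored=True, source="simulated_observation", cap_s=cap_s)
            )
            continue
        lat = 0.0
        if latency_sd_s > 0:
            z = rng.standard_normal()
            while abs(z) > 2.0:  # truncate at +/- 2 sd, keeping zero mean
                z = rng.standard_normal()
            lat = latency_sd_s * z
        obs = max(1e-3, scenario.true_endpoint_s + lat)
        if obs > cap_s:
            results.append(
                EndpointResult(None, censored=True, source="simulated_observation", cap_s=cap_s)
            )
        else:
            results.append(
                EndpointResult(obs, censored=False, source="simulated_observation", cap_s=cap_s)
            )
    return results
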