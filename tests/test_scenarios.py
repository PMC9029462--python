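"""Synthetic scenario generator: packaged parameters, traces, curves, Petri sim."""

import numpy as np
import pytest
from pydantic import ValidationError

from odfkit import CofSignature, FilmScenario, FilmSpec
from odfkit.scenarios import (
    build_scenario,
    mu_profile,
    packaged_flow_params,
    simulate_petri_observation,
    synth_flow_curve,
    synth_friction_trace,
)

# packaged mean disintegration times (s); None = censored beyond 180 s
CELLS = {
    ("C1", "petri"): 25.3, ("C1", "ocm"): None, ("C1", "btm"): 11.0,
    ("C2", "petri"): None, ("C2", "ocm"): None, ("C2", "btm"): 8.0,
    ("P1", "petri"): 7.4, ("P1", "ocm"): 24.0, ("P1", "btm"): 31.0,
    ("P2", "petri"): 22.2, ("P2", "ocm"): None, ("P2", "btm"): 21.0,
}


@pytest.mark.parametrize(("film", "method"), sorted(CELLS))
def test_packaged_scenarios_carry_table_endpoints(film, method):
    scn = build_scenario(film, method)
    expected = CELLS[(film, method)]
    if expected is None:
        assert scn.censored and scn.true_endpoint_s is None
    else:
        assert scn.true_endpoint_s == pytest.approx(expected)
    assert (scn.cof_signature is not None) == (method == "btm")
    assert scn.duration_s <= 180.0


def test_unknown_film_or_method_rejected():
    with pytest.raises(ValueError, match="unknown film_id"):
        build_scenario("X9", "ocm")
    with pytest.raises(ValueError, match="unknown method"):
        build_scenario("P1", "dish")


def test_invalid_overrides_rejected():
    with pytest.raises(ValidationError):
        build_scenario("P1", "ocm", {"duration_s": -5.0})
    with pytest.raises(ValueError, match="truncates before"):
        build_scenario("P1", "ocm", {"duration_s": 10.0})  # endpoint at 24 s


def test_duration_override_truncates_events():
    scn = build_scenario("P2", "ocm", {"duration_s": 78.0})
    assert all(e.onset_s < 78.0 for e in scn.events)
    # the 70 s tear and its 75 s coalesce both survive truncation
    assert {e.kind for e in scn.events} == {"tear", "coalesce"}


def test_scenario_invariants_enforced():
    film = FilmSpec(film_id="P1", polymer="PVA", mw_kda=39, conc_pct_wv=5, thickness_um=35)
    with pytest.raises(ValidationError, match="coalesce"):
        FilmScenario(
            film=film,
            method="ocm",
            duration_s=60,
            censored=True,
            events=[{"kind": "coalesce", "onset_s": 10, "params": {"target_onset_s": 5.0}}],
        )
    with pytest.raises(ValidationError, match="mu_plateau"):
        CofSignature(shape="decline_plateau", mu_initial=0.3, mu_plateau=0.5, transition_s=8)
    with pytest.raises(ValidationError, match="cof_signature"):
        FilmScenario(film=film, method="ocm", duration_s=60, censored=True,
                     cof_signature=CofSignature(shape="decline_plateau", mu_initial=0.5,
                                                mu_plateau=0.3, transition_s=8))


# ---------------------------------------------------------------------------
# friction traces


def _constant_mu_scenario(mu=0.3, duration=60.0):
    sig = {
        "shape": "fluctuate_plateau",
        "mu_initial": mu,
        "mu_plateau": mu,
        "transition_s": duration - 1.0,
        "fluctuation_amp": 0.0,
        "noise_sd": 0.0,
    }
    return build_scenario("P1", "btm", {"duration_s": duration, "cof_signature": sig, "events": []})


def test_trace_sampling_rate():
    scn = _constant_mu_scenario(duration=60.0)
    trace = synth_friction_trace(scn, seed=0)
    assert trace.t_s.size == 6000  # 60 s at 100 Hz
    assert np.allclose(np.diff(trace.t_s), 0.01)


def test_noiseless_constant_mu_ratio_exact():
    trace = synth_friction_trace(_constant_mu_scenario(mu=0.3), seed=1)
    ratio = np.hypot(trace.ff1_N, trace.ff2_N) / trace.fn_N
    assert np.allclose(ratio, 0.3, atol=1e-12)


def test_trace_rejects_non_btm():
    with pytest.raises(ValueError, match="btm"):
        synth_friction_trace(build_scenario("P1", "ocm"), seed=0)


def test_sample_level_changepoint_matches_exhaustive_scan():
    """A near-step decline signature puts the least-squares change-point at
    the scripted transition (exhaustive single-change-point scan oracle)."""
    sig = {
        "shape": "decline_plateau",
        "mu_initial": 0.4,
        "mu_plateau": 0.18,
        "transition_s": 8.0,
        "decline_s": 0.015,  # sharper than one 100 Hz sample: a clean step
        "noise_sd": 0.0,
    }
    scn = build_scenario("C2", "btm", {"duration_s": 20.0, "cof_signature": sig, "events": []})
    trace = synth_friction_trace(scn, seed=0, fn_noise_sd=0.0)
    mu = np.hypot(trace.ff1_N, trace.ff2_N) / trace.fn_N
    # brute-force scan over every split position
    best_c, best_sse = None, np.inf
    for c in range(1, mu.size):
        sse = np.sum((mu[:c] - mu[:c].mean()) ** 2) + np.sum((mu[c:] - mu[c:].mean()) ** 2)
        if sse < best_sse:
            best_c, best_sse = c, sse
    assert trace.t_s[best_c] == pytest.approx(8.0, abs=0.02)


def test_fluctuate_signature_oscillates_then_plateaus():
    sig = CofSignature(
        shape="fluctuate_plateau", mu_initial=0.8, mu_plateau=0.55,
        transition_s=31.0, fluctuation_amp=0.08, fluctuation_period_s=12.0,
    )
    t = np.arange(0, 45, 0.01)
    mu = mu_profile(sig, t)
    pre = mu[t < 31.0]
    assert pre.max() > 0.85 and pre.min() < 0.75  # oscillation around mu_initial
    assert np.allclose(mu[t >= 31.0], 0.55)


def test_trace_seed_determinism():
    scn = build_scenario("C1", "btm")
    a = synth_friction_trace(scn, seed=11)
    b = synth_friction_trace(scn, seed=11)
    c = synth_friction_trace(scn, seed=12)
    assert np.array_equal(a.ff1_N, b.ff1_N)
    assert not np.array_equal(a.ff1_N, c.ff1_N)


# ---------------------------------------------------------------------------
# flow curves


def test_flow_curve_matches_rheometry_protocol():
    curve = synth_flow_curve({"model": "power_law", "K": 2.0, "n": 0.6}, seed=0)
    assert len(curve) == 30
    assert curve.shear_rate_1_per_s[0] == 0.01
    assert curve.shear_rate_1_per_s[-1] == 100.0
    steps = np.diff(np.log10(curve.shear_rate_1_per_s))
    assert np.allclose(steps, steps[0], atol=1e-9)  # logarithmic ascent


def test_newtonian_limit_constant_viscosity():
    curve = synth_flow_curve({"model": "power_law", "K": 2.0, "n": 1.0}, seed=0)
    assert np.allclose(curve.viscosity_Pa_s, 2.0)


def test_power_law_loglog_slope_finite_difference_oracle():
    curve = synth_flow_curve({"model": "power_law", "K": 10.0, "n": 0.5}, seed=0)
    x, y = np.log(curve.shear_rate_1_per_s), np.log(curve.viscosity_Pa_s)
    slopes = np.diff(y) / np.diff(x)
    assert np.allclose(slopes, -0.5, atol=1e-9)


def test_flow_curve_parameter_errors():
    with pytest.raises(ValueError, match="K"):
        synth_flow_curve({"model": "power_law", "K": -1.0, "n": 0.5}, seed=0)
    with pytest.raises(ValueError, match="eta_inf"):
        synth_flow_curve(
            {"model": "cross", "eta0": 0.1, "eta_inf": 0.5, "lam": 1.0, "m": 1.0}, seed=0
        )
    with pytest.raises(ValueError, match="model"):
        synth_flow_curve({"model": "bingham"}, seed=0)


def test_packaged_flow_params_cover_all_films():
    for film in ("C1", "C2", "P1", "P2"):
        params = packaged_flow_params(film)
        curve = synth_flow_curve(params, seed=0)
        assert len(curve) == 30


# ---------------------------------------------------------------------------
# Petri observations


def test_petri_noiseless_observation_is_exact():
    scn = build_scenario("P1", "petri")
    (res,) = simulate_petri_observation(scn, 1, seed=0, latency_sd_s=0.0)
    assert res.time_s == pytest.approx(7.4)
    assert res.source == "simulated_observation"


def test_petri_censored_scenario_always_censored():
    scn = build_scenario("C2", "petri")
    results = simulate_petri_observation(scn, 5, seed=0)
    assert all(r.censored for r in results)
    assert all(r.render() == ">180.0" for r in results)


def test_petri_default_latency_reproduces_observed_spread():
    scn = build_scenario("P1", "petri")
    obs = [
        r.time_s
        for seed in range(5)
        for r in simulate_petri_observation(scn, 3, seed=seed)
    ]
    assert np.mean(obs) == pytest.approx(7.4, abs=0.6)


def test_petri_replicate_count_validated():
    with pytest.raises(ValueError):
        simulate_petri_observation(build_scenario("P1", "petri"), 0, seed=0)
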