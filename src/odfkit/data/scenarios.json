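{
  "comment": "Packaged film scenarios for the four printed films (C1, C2: sodium CMC; P1, P2: PVA) under the three disintegration methods (petri, ocm, btm). Endpoint means/sds are the study conditions the generator emulates; event schedules and friction signatures encode the narrative disintegration archetypes. Edit here, not in code.",
  "films": {
    "C1": {"polymer": "CMC", "mw_kda": 395.0, "conc_pct_wv": 1.0, "width_mm": 30.0, "height_mm": 20.0, "thickness_um": 73.63},
    "C2": {"polymer": "CMC", "mw_kda": 725.0, "conc_pct_wv": 1.0, "width_mm": 30.0, "height_mm": 20.0, "thickness_um": 79.54},
    "P1": {"polymer": "PVA", "mw_kda": 39.0, "conc_pct_wv": 5.0, "width_mm": 30.0, "height_mm": 20.0, "thickness_um": 35.25},
    "P2": {"polymer": "PVA", "mw_kda": 197.0, "conc_pct_wv": 5.0, "width_mm": 30.0, "height_mm": 20.0, "thickness_um": 38.78}
  },
  "endpoints": {
    "petri": {
      "C1": {"mean_s": 25.3, "sd_s": 0.7},
      "C2": {"censored": true},
      "P1": {"mean_s": 7.4, "sd_s": 0.6},
      "P2": {"mean_s": 22.2, "sd_s": 0.9}
    },
    "ocm": {
      "C1": {"censored": true},
      "C2": {"censored": true},
      "P1": {"mean_s": 24.0, "sd_s": 2.0},
      "P2": {"censored": true}
    },
    "btm": {
      "C1": {"mean_s": 11.0, "sd_s": 2.0},
      "C2": {"mean_s": 8.0, "sd_s": 2.0},
      "P1": {"mean_s": 31.0, "sd_s": 3.0},
      "P2": {"mean_s": 21.0, "sd_s": 2.0}
    }
  },
  "durations_s": {
    "petri": {"C1": 40.0, "C2": 180.0, "P1": 20.0, "P2": 35.0},
    "ocm": {"C1": 180.0, "C2": 180.0, "P1": 120.0, "P2": 180.0},
    "btm": {"C1": 30.0, "C2": 30.0, "P1": 60.0, "P2": 45.0}
  },
  "events": {
    "petri": {
      "C1": [
        {"kind": "tear", "onset_s": 25.3, "params": {"region": "vertical", "x_frac": 0.55, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 25.3, "params": {"rate_frac_per_s": 0.02}}
      ],
      "C2": [
        {"kind": "swell", "onset_s": 0.0, "params": {"factor": 1.1, "ramp_s": 150.0}}
      ],
      "P1": [
        {"kind": "tear", "onset_s": 7.4, "params": {"region": "vertical", "x_frac": 0.5, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 7.4, "params": {"rate_frac_per_s": 0.03}}
      ],
      "P2": [
        {"kind": "tear", "onset_s": 22.2, "params": {"region": "vertical", "x_frac": 0.45, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 22.2, "params": {"rate_frac_per_s": 0.02}}
      ]
    },
    "ocm": {
      "C1": [
        {"kind": "swell", "onset_s": 0.0, "params": {"factor": 1.12, "ramp_s": 120.0}}
      ],
      "C2": [
        {"kind": "swell", "onset_s": 0.0, "params": {"factor": 1.15, "ramp_s": 120.0}}
      ],
      "P1": [
        {"kind": "detach", "onset_s": 24.0, "params": {"area_frac": 0.18, "gap_px": 4, "speed_px_s": 30.0, "leave_px": 160.0}},
        {"kind": "shrink", "onset_s": 24.0, "params": {"rate_frac_per_s": 0.008}}
      ],
      "P2": [
        {"kind": "tear", "onset_s": 70.0, "params": {"region": "corner", "area_frac": 0.06, "gap_px": 3, "split_s": 0.1}},
        {"kind": "coalesce", "onset_s": 75.0, "params": {"target_onset_s": 70.0}},
        {"kind": "tear", "onset_s": 80.0, "params": {"region": "corner", "area_frac": 0.06, "gap_px": 3, "split_s": 0.1}},
        {"kind": "coalesce", "onset_s": 85.0, "params": {"target_onset_s": 80.0}},
        {"kind": "tear", "onset_s": 95.0, "params": {"region": "corner", "area_frac": 0.07, "gap_px": 3, "split_s": 0.1}},
        {"kind": "coalesce", "onset_s": 100.0, "params": {"target_onset_s": 95.0}},
        {"kind": "tear", "onset_s": 105.0, "params": {"region": "vertical", "x_frac": 0.62, "gap_px": 4, "split_s": 0.1}},
        {"kind": "coalesce", "onset_s": 160.0, "params": {"target_onset_s": 105.0}}
      ]
    },
    "btm": {
      "C1": [
        {"kind": "tear", "onset_s": 11.0, "params": {"region": "vertical", "x_frac": 0.5, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 11.0, "params": {"rate_frac_per_s": 0.03}}
      ],
      "C2": [
        {"kind": "tear", "onset_s": 8.0, "params": {"region": "vertical", "x_frac": 0.5, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 8.0, "params": {"rate_frac_per_s": 0.035}}
      ],
      "P1": [
        {"kind": "tear", "onset_s": 31.0, "params": {"region": "vertical", "x_frac": 0.4, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 31.0, "params": {"rate_frac_per_s": 0.02}}
      ],
      "P2": [
        {"kind": "tear", "onset_s": 21.0, "params": {"region": "vertical", "x_frac": 0.55, "gap_px": 4}},
        {"kind": "shrink", "onset_s": 21.0, "params": {"rate_frac_per_s": 0.02}}
      ]
    }
  },
  "cof_signatures": {
    "C1": {"shape": "decline_plateau", "mu_initial": 0.45, "mu_plateau": 0.25, "transition_s": 11.0, "decline_s": 2.0, "fluctuation_amp": 0.0, "noise_sd": 0.02},
    "C2": {"shape": "decline_plateau", "mu_initial": 0.40, "mu_plateau": 0.18, "transition_s": 8.0, "decline_s": 2.0, "fluctuation_amp": 0.0, "noise_sd": 0.02},
    "P1": {"shape": "fluctuate_plateau", "mu_initial": 0.80, "mu_plateau": 0.55, "transition_s": 31.0, "decline_s": 2.0, "fluctuation_amp": 0.08, "fluctuation_period_s": 12.0, "noise_sd": 0.02},
    "P2": {"shape": "fluctuate_plateau", "mu_initial": 0.75, "mu_plateau": 0.50, "transition_s": 21.0, "decline_s": 2.0, "fluctuation_amp": 0.12, "fluctuation_period_s": 10.0, "noise_sd": 0.02}
  },
  "rheology": {
    "comment": "Plausible stand-in flow-curve parameters (no numerical flow data are published): CMC solutions shear-thin over the whole range, PVA solutions plateau at moderate shear.",
    "C1": {"model": "power_law", "K": 1.5, "n": 0.55},
    "C2": {"model": "power_law", "K": 30.0, "n": 0.35},
    "P1": {"model": "cross", "eta0": 0.5, "eta_inf": 0.06, "lam": 0.1, "m": 1.3},
    "P2": {"model": "cross", "eta0": 1.5, "eta_inf": 0.12, "lam": 0.8, "m": 1.1}
  },
  "btm_rig": {"freq_hz": 1.0, "load_n": 1.0, "stroke_mm": 7.5, "sample_rate_hz": 100.0, "ssf_volume_ul": 100.0, "ssf_strokes_per_dose": 4},
  "ocm_rig": {"compression_period_s": 2.0, "irrigation_ml_per_min": 1.5},
  "petri_obs": {"latency_trunc_sigmas": 2.0}
}
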