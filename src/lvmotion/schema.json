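{
  "profile_csv": {
    "description": "Per-frame normalized fit results written by fit_series / the `fit` CLI verb.",
    "columns": {
      "phase_fraction": "Cardiac phase Delta t / T_cardiac, dimensionless, in [0, 1).",
      "alpha_norm": "Fitted radial contraction parameter scaled by the epicardial radius (alpha / r_epi), dimensionless, >= 0.",
      "beta_norm": "Fitted rotation parameter scaled by the epicardial radius (beta / r_epi); positive = clockwise viewed head-to-toe.",
      "F_best": "Figure-of-merit at the fitted parameters, in [0, 1]; 0 is a perfect mesh/tag match.",
      "merit_reduction_pct": "100 * (F_initial - F_best) / F_initial, where F_initial is the merit of the null model (0, 0).",
      "alpha_norm_sd": "(aggregated profiles only) sample SD of alpha_norm across subjects, n-1 denominator.",
      "beta_norm_sd": "(aggregated profiles only) sample SD of beta_norm across subjects.",
      "n_subjects": "(aggregated profiles only) number of subjects averaged."
    },
    "sidecar_json": "Same basename with .json: slice_level, r_epi_mm, grid specification and software version."
  },
  "marker_report_json": {
    "description": "Per-phase derived markers written by build_report / the `report` CLI verb.",
    "fields": {
      "slice_level": "apex | mid | base or a slice index label.",
      "r_epi_mm": "End-diastolic epicardial radius, mm.",
      "r_endo_mm": "End-diastolic endocardial radius, mm.",
      "per_phase": [
        {
          "phase_fraction": "Cardiac phase, dimensionless.",
          "radius_change_endo_mm": "Endocardial radius decrease alpha^2 / r_endo, mm.",
          "cavity_area_reduction_mm2": "Exact cavity cross-sectional area reduction pi * (r_endo^2 - r'^2), mm^2.",
          "cavity_area_fraction": "Area reduction relative to the end-diastolic cavity area."
        }
      ],
      "twist_apex_base": [
        {
          "phase_fraction": "Cardiac phase, dimensionless.",
          "twist_norm": "beta_norm(apex) - beta_norm(base); positive = apex clockwise relative to base (head-to-toe view).",
          "twist_epi_deg": "The same difference expressed as the epicardial rotation-angle difference in degrees."
        }
      ]
    }
  },
  "ground_truth_csv": {
    "description": "Written by the `simulate` CLI verb next to the rendered frames.",
    "columns": {
      "phase_fraction": "Cardiac phase of each frame.",
      "alpha_norm": "Generating alpha / r_epi per frame.",
      "beta_norm": "Generating beta / r_epi per frame."
    }
  }
}
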