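{
  "description": "Ten fictitious validation cases with the automatic and blinded-expert decision strings (dashes normalized to ASCII).",
  "fixtures": [
    {
      "case": {"case_id": "T1-01", "site": "larynx_glottic", "tnm": "T1N0M0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": true,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Radiation or surgery",
      "expected_expert": "Radiation or surgery"
    },
    {
      "case": {"case_id": "T1-02", "site": "nasopharynx", "tnm": "T2N0M0",
               "histology": "ucnt", "surgery_feasible": true,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Radiation and chemotherapy",
      "expected_expert": "Radiation and chemotherapy"
    },
    {
      "case": {"case_id": "T1-03", "site": "oral_tongue", "tnm": "T2N0M0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": true,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Surgery or radiation",
      "expected_expert": "Surgery and radiation"
    },
    {
      "case": {"case_id": "T1-04", "site": "oropharynx", "tnm": "T3N1M0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": true,
               "radiation_feasible": false, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Face-to-face MDMs",
      "expected_expert": "Face-to-face MDMs"
    },
    {
      "case": {"case_id": "T1-05", "site": "tongue_base", "tnm": "T4N2cM1",
               "histology": "epidermoid_carcinoma", "surgery_feasible": false,
               "radiation_feasible": true, "chemotherapy_feasible": false,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Face-to-face MDM",
      "expected_expert": "Face-to-face MDM"
    },
    {
      "case": {"case_id": "T1-06", "site": "larynx_supraglottic", "tnm": "T2N0M0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": true,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Surgery + radiation or radiation",
      "expected_expert": "Surgery ± radiation"
    },
    {
      "case": {"case_id": "T1-07", "site": "floor_of_mouth", "tnm": "T3N1M0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": false,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Radiation + chemotherapy",
      "expected_expert": "Radiation + chemotherapy"
    },
    {
      "case": {"case_id": "T1-08", "site": "oropharynx", "tnm": "T2N0M0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": true,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Surgery + radiation or radiation + chemotherapy",
      "expected_expert": "Surgery + radiation"
    },
    {
      "case": {"case_id": "T1-09", "site": "nasopharynx", "tnm": "T3N2M0",
               "histology": "ucnt", "surgery_feasible": false,
               "radiation_feasible": true, "chemotherapy_feasible": true,
               "relapse": false, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Radiation + chemotherapy",
      "expected_expert": "Radiation + chemotherapy"
    },
    {
      "case": {"case_id": "T1-10", "site": "hypopharynx", "tnm": "T3N2cM0",
               "histology": "epidermoid_carcinoma", "surgery_feasible": false,
               "radiation_feasible": false, "chemotherapy_feasible": true,
               "relapse": true, "poor_prognosis_factors": [],
               "submitted_by": "fixture", "submitted_at": null},
      "expected_auto": "Face-to-face MDM",
      "expected_expert": "Face-to-face MDM"
    }
  ]
}
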