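{
  "version": 1,
  "description": "NCCN-style therapeutic options per (sublocation, stage class) before feasibility filtering. Metastatic disease and relapse always escalate to a face-to-face meeting and have no entries here. Entries marked anchored=false are pattern-completed cells not pinned by a published test case; edit with care.",
  "entries": [
    {"site": "larynx_glottic", "stage_class": "early",
     "regimens": [["radiation"], ["surgery"]], "anchored": true},
    {"site": "larynx_glottic", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": false},
    {"site": "larynx_supraglottic", "stage_class": "early",
     "regimens": [["surgery", "radiation"], ["radiation"]], "anchored": true},
    {"site": "larynx_supraglottic", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": false},
    {"site": "nasopharynx", "stage_class": "early",
     "regimens": [["radiation", "chemotherapy"]], "anchored": true},
    {"site": "nasopharynx", "stage_class": "locally_advanced",
     "regimens": [["radiation", "chemotherapy"]], "anchored": true},
    {"site": "oral_tongue", "stage_class": "early",
     "regimens": [["surgery"], ["radiation"]], "anchored": true},
    {"site": "oral_tongue", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": false},
    {"site": "floor_of_mouth", "stage_class": "early",
     "regimens": [["surgery"], ["radiation"]], "anchored": false},
    {"site": "floor_of_mouth", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": true},
    {"site": "oropharynx", "stage_class": "early",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": true},
    {"site": "oropharynx", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": true},
    {"site": "tongue_base", "stage_class": "early",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": false},
    {"site": "tongue_base", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": true},
    {"site": "hypopharynx", "stage_class": "early",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": true},
    {"site": "hypopharynx", "stage_class": "locally_advanced",
     "regimens": [["surgery", "radiation"], ["radiation", "chemotherapy"]], "anchored": true}
  ]
}
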