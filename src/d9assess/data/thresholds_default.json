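{
  "note": "Default regulatory reference values. ML entries are externally sourced from Regulation (EC) No. 1881/2006 and its amendments (629/2008, 420/2011, 835/2011, 1259/2011); EQS entries from the WFD priority-substance EQS directive 2013/39/EU and the EQS dossiers; EAC from OSPAR agreement on TBT in bivalves; national_QS from the Norwegian Environment Agency. Values change with regulation: edit or replace this registry rather than the code.",
  "thresholds": [
    {"analyte": "Pb",       "matrix_class": "bivalve",     "value": 1.5,    "unit": "mg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EC) No. 1881/2006, bivalve molluscs"},
    {"analyte": "Pb",       "matrix_class": "fish_muscle", "value": 0.30,   "unit": "mg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EC) No. 1881/2006, muscle meat of fish"},
    {"analyte": "Cd",       "matrix_class": "bivalve",     "value": 1.0,    "unit": "mg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EC) No. 1881/2006, bivalve molluscs"},
    {"analyte": "Cd",       "matrix_class": "fish_muscle", "value": 0.05,   "unit": "mg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EC) No. 1881/2006, muscle meat of fish"},
    {"analyte": "Hg",       "matrix_class": "bivalve",     "value": 0.50,   "unit": "mg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EC) No. 1881/2006, fishery products"},
    {"analyte": "Hg",       "matrix_class": "fish_muscle", "value": 0.50,   "unit": "mg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EC) No. 1881/2006, muscle meat of fish"},
    {"analyte": "BaP",      "matrix_class": "bivalve",     "value": 5.0,    "unit": "µg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EU) No. 835/2011, bivalve molluscs"},
    {"analyte": "PAH4",     "matrix_class": "bivalve",     "value": 30.0,   "unit": "µg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EU) No. 835/2011, sum of 4 PAHs, bivalve molluscs"},
    {"analyte": "TEQ",      "matrix_class": "fish_muscle", "value": 6.5,    "unit": "pg/g",  "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EU) No. 1259/2011, PCDD/F + dl-PCB WHO-TEQ, muscle meat of fish"},
    {"analyte": "PCDDF-TEQ","matrix_class": "fish_muscle", "value": 3.5,    "unit": "pg/g",  "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EU) No. 1259/2011, PCDD/F WHO-TEQ, muscle meat of fish"},
    {"analyte": "ndl-PCB6", "matrix_class": "fish_muscle", "value": 75.0,   "unit": "µg/kg", "basis": "wet", "kind": "ML",  "protection_goal": "human_health",        "source": "Reg. (EU) No. 1259/2011, sum of 6 indicator PCBs, muscle meat of fish"},
    {"analyte": "PFOS",     "matrix_class": "fish_muscle", "value": 9.1,    "unit": "µg/kg", "basis": "wet", "kind": "EQS", "protection_goal": "human_health",        "source": "Directive 2013/39/EU, biota EQS for fish"},
    {"analyte": "PBDE6",    "matrix_class": "fish_muscle", "value": 0.0085, "unit": "µg/kg", "basis": "wet", "kind": "EQS", "protection_goal": "human_health",        "source": "Directive 2013/39/EU, sum of BDE-28/47/99/100/153/154, biota EQS for fish"},
    {"analyte": "HBCDD",    "matrix_class": "fish_muscle", "value": 167.0,  "unit": "µg/kg", "basis": "wet", "kind": "EQS", "protection_goal": "secondary_poisoning", "source": "Directive 2013/39/EU, biota EQS for fish"},
    {"analyte": "HBCDD",    "matrix_class": "fish_muscle", "value": 6100.0, "unit": "µg/kg", "basis": "wet", "kind": "EQS", "protection_goal": "human_health",        "source": "EQS dossier HBCDD, quality standard for human health via fishery consumption"},
    {"analyte": "TBT",      "matrix_class": "bivalve",     "value": 12.0,   "unit": "µg/kg", "basis": "dry", "kind": "EAC", "protection_goal": "secondary_poisoning", "source": "OSPAR EAC for TBT in bivalves"},
    {"analyte": "TBT",      "matrix_class": "fish_muscle", "value": 150.0,  "unit": "µg/kg", "basis": "wet", "kind": "national_QS", "protection_goal": "secondary_poisoning", "source": "Norwegian Environment Agency biota quality standard for TBT compounds"}
  ]
}
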