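{
  "provenance": "WHO-2005 (Van den Berg et al. 2006, Toxicol Sci 93:223-241)",
  "note": "Toxic equivalency factors for the 2005 WHO re-evaluation; reference congener 2,3,7,8-TCDD has TEF 1. Externally sourced reference table, replaceable via config.",
  "congeners": {
    "2378-TCDD":     {"tef": 1.0,     "class": "dioxin"},
    "12378-PeCDD":   {"tef": 1.0,     "class": "dioxin"},
    "123478-HxCDD":  {"tef": 0.1,     "class": "dioxin"},
    "123678-HxCDD":  {"tef": 0.1,     "class": "dioxin"},
    "123789-HxCDD":  {"tef": 0.1,     "class": "dioxin"},
    "1234678-HpCDD": {"tef": 0.01,    "class": "dioxin"},
    "OCDD":          {"tef": 0.0003,  "class": "dioxin"},
    "2378-TCDF":     {"tef": 0.1,     "class": "furan"},
    "12378-PeCDF":   {"tef": 0.03,    "class": "furan"},
    "23478-PeCDF":   {"tef": 0.3,     "class": "furan"},
    "123478-HxCDF":  {"tef": 0.1,     "class": "furan"},
    "123678-HxCDF":  {"tef": 0.1,     "class": "furan"},
    "123789-HxCDF":  {"tef": 0.1,     "class": "furan"},
    "234678-HxCDF":  {"tef": 0.1,     "class": "furan"},
    "1234678-HpCDF": {"tef": 0.01,    "class": "furan"},
    "1234789-HpCDF": {"tef": 0.01,    "class": "furan"},
    "OCDF":          {"tef": 0.0003,  "class": "furan"},
    "PCB-77":        {"tef": 0.0001,  "class": "dl-pcb"},
    "PCB-81":        {"tef": 0.0003,  "class": "dl-pcb"},
    "PCB-126":       {"tef": 0.1,     "class": "dl-pcb"},
    "PCB-169":       {"tef": 0.03,    "class": "dl-pcb"},
    "PCB-105":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-114":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-118":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-123":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-156":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-157":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-167":       {"tef": 0.00003, "class": "dl-pcb"},
    "PCB-189":       {"tef": 0.00003, "class": "dl-pcb"}
  }
}
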