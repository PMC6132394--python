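{
  "note": "Mean matrix composition per monitoring site for blue-mussel soft-body pools: tissue water content and share of pooled wet weight contributed by retained breathing water. NS1 = Lower Saxony Wadden Sea, NS2 = Schleswig-Holstein Wadden Sea, BS = Baltic Sea / Western Pomerania.",
  "sites": {
    "NS1": {"water_fraction": 0.906, "breathing_water_fraction": 0.67},
    "NS2": {"water_fraction": 0.926, "breathing_water_fraction": 0.58},
    "BS":  {"water_fraction": 0.947, "breathing_water_fraction": 0.67}
  }
}
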