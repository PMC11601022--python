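{
  "$id": "sf6mbw-outcomes-v1",
  "title": "MBW outcomes report",
  "type": "object",
  "required": [
    "frc_ml",
    "cev_ml",
    "lci_to",
    "end_of_test_breath",
    "breath_count_to_end",
    "initial_end_tidal_sf6",
    "final_end_tidal_sf6",
    "end_tidal_sf6",
    "dead_space_ml",
    "clamped_sample_fraction",
    "flags",
    "schema",
    "software_version"
  ],
  "properties": {
    "frc_ml": {"type": "number"},
    "cev_ml": {"type": "number"},
    "lci_to": {"type": "number"},
    "end_of_test_breath": {"type": "integer"},
    "breath_count_to_end": {"type": "integer"},
    "initial_end_tidal_sf6": {"type": "number"},
    "final_end_tidal_sf6": {"type": "number"},
    "end_tidal_sf6": {"type": "array"},
    "dead_space_ml": {"type": "number"},
    "clamped_sample_fraction": {"type": "number"},
    "flags": {"type": "array"},
    "schema": {"type": "string"},
    "software_version": {"type": "string"},
    "config": {"type": "object"}
  }
}
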