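[
 {"name": "ethanol", "unit": "%", "low": 40, "center": 60, "high": 80},
 {"name": "temperature", "unit": "degC", "low": 70, "center": 80, "high": 90},
 {"name": "ratio", "unit": "mL g-1", "low": 20, "center": 25, "high": 30},
 {"name": "time", "unit": "min", "low": 60, "center": 90, "high": 120}
]
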