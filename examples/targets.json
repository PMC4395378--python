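[
 {"id": "na_conduction_threshold", "check": "na_conduction_threshold", "expected": 81.0, "tol": 1.0},
 {"id": "k_conduction_min", "check": "k_conduction_min", "expected": 3.0, "tol": 1.0},
 {"id": "k_conduction_max", "check": "k_conduction_max", "expected": 88.0, "tol": 1.0},
 {"id": "type3_boundary", "check": "type3_boundary", "expected": 24.0, "tol": 1.0}
]
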