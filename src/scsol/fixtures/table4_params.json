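{
  "chrastil": {"kappa": 3.2364, "A1": -14.548, "B1": -2624.0},
  "reformulated_chrastil": {"kappa": 3.2439, "A2": -17.896, "B2": -1910.2},
  "mst": {"A3": -6486.6, "B3": 2.193, "C3": 10.103},
  "bartle": {"A4": 9.8241, "B4": -4861.2, "C4": 0.0065735},
  "kj": {"A5": -4.197, "B5": 0.0031559, "C5": -2671.2},
  "association": {"kappa": 1.1945, "A6": -1519.5, "B6": 2.1846, "C6": 0.0024843, "D6": -20.894},
  "metrics": {
    "chrastil": {"r2": 0.92249, "r2_adj": 0.91951, "aard_percent": 4.97},
    "reformulated_chrastil": {"r2": 0.96697, "r2_adj": 0.96570, "aard_percent": 4.95},
    "mst": {"r2": 0.91635, "r2_adj": 0.9059, "aard_percent": 8.721},
    "bartle": {"r2": 0.89618, "r2_adj": 0.89219, "aard_percent": 9.06},
    "kj": {"r2": 0.98536, "r2_adj": 0.98480, "aard_percent": 3.16},
    "association": {"r2": 0.98817, "r2_adj": 0.98772, "aard_percent": 2.53}
  }
}
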