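{
  "_comment": "Acceptance pattern for the expression profile of each genotype. 'ordered' lists the genes whose expression windows must appear in this onset order; genes not listed and not clamped ON must never be expressed. 'strict_pairs' are adjacent pairs whose onsets may not coincide (all other adjacent onsets may tie, but no two expressed genes may occupy an identical window). 'persist' requires the final listed gene to remain ON through the end of the simulation; it is dropped only for cas overexpression, where every activator of Kr disappears and the reported Kr window is transient.",
  "criteria": [
    {"genotype": "wt",
     "ordered": ["hb", "Kr", "pdm", "cas"],
     "strict_pairs": [], "persist": true},
    {"genotype": "hb-",
     "ordered": ["Kr", "pdm", "cas"],
     "strict_pairs": [["pdm", "cas"]], "persist": true},
    {"genotype": "Kr-",
     "ordered": ["hb", "pdm", "cas"],
     "strict_pairs": [], "persist": true},
    {"genotype": "pdm-",
     "ordered": ["hb", "Kr", "cas"],
     "strict_pairs": [], "persist": true},
    {"genotype": "cas-",
     "ordered": ["hb", "Kr", "pdm"],
     "strict_pairs": [], "persist": true},
    {"genotype": "hb++",
     "ordered": ["Kr"],
     "strict_pairs": [], "persist": true},
    {"genotype": "Kr++",
     "ordered": ["hb", "pdm"],
     "strict_pairs": [], "persist": true},
    {"genotype": "pdm++",
     "ordered": ["hb", "cas"],
     "strict_pairs": [], "persist": true},
    {"genotype": "cas++",
     "ordered": ["hb", "Kr"],
     "strict_pairs": [], "persist": false}
  ]
}
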