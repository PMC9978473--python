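{
  "schema_version": 1,
  "description": "Default 20-level head-and-neck lymph node level taxonomy: midline levels Ia, VIa, VIb, VIIa and bilateral levels Ib, II, III, IVa, IVb, V, VIIb, VIII (left/right). Label values are contiguous 1-20; background is 0, giving 21 classes in total. Exclusivity chains list craniocaudally adjacent levels per side (cranial to caudal).",
  "background_value": 0,
  "entries": [
    {"name": "Ia",        "label_value": 1,  "laterality": "midline"},
    {"name": "VIa",       "label_value": 2,  "laterality": "midline"},
    {"name": "VIb",       "label_value": 3,  "laterality": "midline"},
    {"name": "VIIa",      "label_value": 4,  "laterality": "midline"},
    {"name": "Ib_left",   "label_value": 5,  "laterality": "left"},
    {"name": "Ib_right",  "label_value": 6,  "laterality": "right"},
    {"name": "II_left",   "label_value": 7,  "laterality": "left"},
    {"name": "II_right",  "label_value": 8,  "laterality": "right"},
    {"name": "III_left",  "label_value": 9,  "laterality": "left"},
    {"name": "III_right", "label_value": 10, "laterality": "right"},
    {"name": "IVa_left",  "label_value": 11, "laterality": "left"},
    {"name": "IVa_right", "label_value": 12, "laterality": "right"},
    {"name": "IVb_left",  "label_value": 13, "laterality": "left"},
    {"name": "IVb_right", "label_value": 14, "laterality": "right"},
    {"name": "V_left",    "label_value": 15, "laterality": "left"},
    {"name": "V_right",   "label_value": 16, "laterality": "right"},
    {"name": "VIIb_left", "label_value": 17, "laterality": "left"},
    {"name": "VIIb_right","label_value": 18, "laterality": "right"},
    {"name": "VIII_left", "label_value": 19, "laterality": "left"},
    {"name": "VIII_right","label_value": 20, "laterality": "right"}
  ],
  "mirror_pairs": [
    ["Ib_left", "Ib_right"],
    ["II_left", "II_right"],
    ["III_left", "III_right"],
    ["IVa_left", "IVa_right"],
    ["IVb_left", "IVb_right"],
    ["V_left", "V_right"],
    ["VIIb_left", "VIIb_right"],
    ["VIII_left", "VIII_right"]
  ],
  "exclusivity_chains": [
    ["II_left", "III_left", "IVa_left", "IVb_left"],
    ["II_right", "III_right", "IVa_right", "IVb_right"]
  ]
}
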