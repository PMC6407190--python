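{
  "description": [
    "Event script for the formation of the 7 Triticeae (T) chromosomes from the",
    "12-chromosome reference karyotype: 4 nested chromosome fusions, 1 end-end",
    "joining, 1 reciprocal translocation between the two intermediates, then loss",
    "of all 5 satellite chromosomes. Cut positions are fractions of the current",
    "gene count; insertion points default to the recipient's centromere.",
    "The nesting directions of the T2 (Os4+Os7) and T7 (Os6+Os8) fusions are",
    "figure-derived (the text gives only the aggregate '4 NCFs and 1 end-end",
    "merge'); they are encoded as NCFs with the smaller-numbered chromosome as",
    "recipient, which does not affect event counts or homoeology flags."
  ],
  "homoeolog_pairs": [
    ["Os1", "Os5"], ["Os2", "Os10"], ["Os3", "Os7"],
    ["Os4", "Os6"], ["Os8", "Os9"], ["Os11", "Os12"]
  ],
  "events": [
    {"type": "NCF", "donor": "Os10", "recipient": "Os5",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "T1"},
    {"type": "NCF", "donor": "Os7", "recipient": "Os4",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "T2"},
    {"type": "NCF", "donor": "Os8", "recipient": "Os6",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "T7"},
    {"type": "NCF", "donor": "Os11", "recipient": "Os3",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Os11/Os3"},
    {"type": "EEJ", "a": "Os12", "b": "Os9",
     "cut_a": 0.9, "cut_b": 0.1, "product": "Os12/Os9"},
    {"type": "RECIPROCAL_TRANSLOCATION", "a": "Os11/Os3", "b": "Os12/Os9",
     "cut_a": 0.85, "cut_b": 0.6, "products": ["T4", "T5"]},
    {"type": "DROP_SATELLITES"}
  ],
  "final_names": {"Os1": "T3", "Os2": "T6"}
}
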