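{
  "description": [
    "Event script for the formation of the 5 Brachypodium (Bd) chromosomes from",
    "the 12-chromosome reference karyotype: 7 nested chromosome fusions followed",
    "by loss of all 7 satellite chromosomes. Bd5 is the untouched Os4.",
    "For the Bd1, Bd3 and Bd4 double nestings the temporal order of the two",
    "insertions is undetermined (either order yields the same final paint); the",
    "script fixes one order arbitrarily."
  ],
  "homoeolog_pairs": [
    ["Os1", "Os5"], ["Os2", "Os10"], ["Os3", "Os7"],
    ["Os4", "Os6"], ["Os8", "Os9"], ["Os11", "Os12"]
  ],
  "events": [
    {"type": "NCF", "donor": "Os7", "recipient": "Os3",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Os7/Os3"},
    {"type": "NCF", "donor": "Os6", "recipient": "Os7/Os3",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Bd1"},
    {"type": "NCF", "donor": "Os5", "recipient": "Os1",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Bd2"},
    {"type": "NCF", "donor": "Os8", "recipient": "Os2",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Os8/Os2"},
    {"type": "NCF", "donor": "Os10", "recipient": "Os8/Os2",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Bd3"},
    {"type": "NCF", "donor": "Os11", "recipient": "Os9",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Os11/Os9"},
    {"type": "NCF", "donor": "Os12", "recipient": "Os11/Os9",
     "donor_cuts": [0.1, 0.9], "insertion_point": "centromere", "product": "Bd4"},
    {"type": "DROP_SATELLITES"}
  ],
  "final_names": {"Os4": "Bd5"}
}
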