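{
  "_comment": [
    "Projection of the 12 reference (Os) chromosomes onto ancestral",
    "proto-chromosome labels, consistent with rice_homoeolog_pairs.json:",
    "the two members of each homoeologous pair project to one proto label.",
    "This correspondence is an editable assumption shipped as config."
  ],
  "map": {
    "Os1": "A1",
    "Os5": "A1",
    "Os2": "A2",
    "Os10": "A2",
    "Os3": "A3",
    "Os7": "A3",
    "Os4": "A4",
    "Os6": "A4",
    "Os8": "A5",
    "Os9": "A5",
    "Os11": "A6",
    "Os12": "A6"
  }
}
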