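{
  "_comment": [
    "Homoeologous chromosome pairs of the 12-chromosome reference (rice-like)",
    "karyotype, descended from 7 proto-chromosome pairs through the grass-common",
    "whole-genome duplication. The literature's duplicated blocks are not a",
    "perfect matching (Os2 pairs with both Os4 and Os6, Os3 with both Os7 and",
    "Os10 at the segment level); the flagging logic needs a matching, so this",
    "file simplifies to one, keeping the four unambiguous literature pairs",
    "(1-5, 3-7, 8-9, 11-12). Editable config, not code."
  ],
  "pairs": [
    ["Os1", "Os5"],
    ["Os2", "Os10"],
    ["Os3", "Os7"],
    ["Os4", "Os6"],
    ["Os8", "Os9"],
    ["Os11", "Os12"]
  ]
}
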