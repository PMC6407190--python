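{
  "_comment": [
    "Chromosome color palette for dotplots and karyograms. The seven ancestral",
    "proto-chromosome colors follow the widely reused grass scheme in spirit;",
    "exact hex values are an approximation chosen for distinctness. Reference",
    "chromosomes reuse their proto color family with a light/dark split per",
    "homoeolog. Editable config."
  ],
  "labels": {
    "A1": "#e41a1c", "A2": "#377eb8", "A3": "#4daf4a", "A4": "#984ea3",
    "A5": "#ff7f00", "A6": "#a65628", "A7": "#f781bf",
    "Os1": "#e41a1c", "Os5": "#fb6a4a",
    "Os2": "#377eb8", "Os10": "#6baed6",
    "Os3": "#4daf4a", "Os7": "#a1d99b",
    "Os4": "#984ea3", "Os6": "#bcbddc",
    "Os8": "#ff7f00", "Os9": "#fdae6b",
    "Os11": "#a65628", "Os12": "#d8b365"
  },
  "ranks": {"best": "#d62728", "second": "#1f77b4", "other": "#bbbbbb"},
  "classes": {"primary": "#d62728", "secondary": "#1f77b4", "other": "#bbbbbb"}
}
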