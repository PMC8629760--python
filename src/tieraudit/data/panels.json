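[
 {
  "panel_id": "craniosynostosis",
  "version_tag": "original",
  "entries": [
   {"gene": "FGFR2", "rating": "green", "moi": "monoallelic"},
   {"gene": "FGFR3", "rating": "green", "moi": "monoallelic"},
   {"gene": "TWIST1", "rating": "green", "moi": "monoallelic"},
   {"gene": "ERF", "rating": "green", "moi": "monoallelic"},
   {"gene": "TCF12", "rating": "green", "moi": "monoallelic"}
  ]
 },
 {
  "panel_id": "craniosynostosis",
  "version_tag": "updated",
  "entries": [
   {"gene": "FGFR2", "rating": "green", "moi": "monoallelic"},
   {"gene": "FGFR3", "rating": "green", "moi": "monoallelic"},
   {"gene": "TWIST1", "rating": "green", "moi": "monoallelic"},
   {"gene": "ERF", "rating": "green", "moi": "monoallelic"},
   {"gene": "TCF12", "rating": "green", "moi": "monoallelic"},
   {"gene": "SMAD6", "rating": "green", "moi": "monoallelic"},
   {"gene": "TRAF7", "rating": "green", "moi": "monoallelic"},
   {"gene": "PTCH1", "rating": "amber", "moi": "monoallelic"},
   {"gene": "GPC3", "rating": "amber", "moi": "x_linked"},
   {"gene": "SOX6", "rating": "red", "moi": "monoallelic"}
  ]
 },
 {
  "panel_id": "dd_syndromes",
  "version_tag": "original",
  "entries": [
   {"gene": "MAN2B1", "rating": "green", "moi": "biallelic"},
   {"gene": "MEGF8", "rating": "green", "moi": "biallelic"},
   {"gene": "MMP21", "rating": "green", "moi": "biallelic"},
   {"gene": "ARID1B", "rating": "green", "moi": "monoallelic"}
  ]
 },
 {
  "panel_id": "dd_syndromes",
  "version_tag": "updated",
  "entries": [
   {"gene": "MAN2B1", "rating": "green", "moi": "biallelic"},
   {"gene": "MEGF8", "rating": "green", "moi": "biallelic"},
   {"gene": "MMP21", "rating": "green", "moi": "biallelic"},
   {"gene": "ARID1B", "rating": "green", "moi": "monoallelic"},
   {"gene": "HNRNPK", "rating": "green", "moi": "monoallelic"},
   {"gene": "FBXO11", "rating": "green", "moi": "monoallelic"},
   {"gene": "OGT", "rating": "green", "moi": "x_linked"}
  ]
 }
]
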