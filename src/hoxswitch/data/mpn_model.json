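{
  "name": "JAK2/TET2/HOXA9 MPN network",
  "variables": [
    {"id": "JAK2", "name": "JAK2", "range_min": 0, "range_max": 2, "target": "1"},
    {"id": "TET2", "name": "TET2", "range_min": 0, "range_max": 2, "target": "1"},
    {"id": "STAT5", "name": "STAT5", "range_min": 0, "range_max": 2, "target": "JAK2"},
    {"id": "MAPK", "name": "MAPK pathway", "range_min": 0, "range_max": 2, "target": "JAK2"},
    {"id": "ITCH", "name": "ITCH", "range_min": 0, "range_max": 2, "target": "MAPK"},
    {"id": "NOTCH", "name": "NOTCH pathway", "range_min": 0, "range_max": 2, "target": "2 - ITCH"},
    {"id": "HOXA9", "name": "HOXA9", "range_min": 0, "range_max": 2, "target": "STAT5 + TET2 + HOXA9 - 2"},
    {"id": "RUNX1", "name": "RUNX1", "range_min": 0, "range_max": 2, "target": "HOXA9"},
    {"id": "SPI1", "name": "SPI1 (PU.1)", "range_min": 0, "range_max": 2, "target": "min(RUNX1, 2 - GATA1)"},
    {"id": "GATA1", "name": "GATA1", "range_min": 0, "range_max": 2, "target": "RUNX1 + min(RUNX1, STAT5) - SPI1"},
    {"id": "KLF1", "name": "KLF1", "range_min": 0, "range_max": 2, "target": "avg(TET2, GATA1)"},
    {"id": "MYB", "name": "MYB", "range_min": 0, "range_max": 2, "target": "2 - avg(SPI1, GATA1)"},
    {"id": "MYC", "name": "MYC", "range_min": 0, "range_max": 2, "target": "2 - GATA1"},
    {"id": "SC_self_renewal", "name": "Stem cell self-renewal", "range_min": 0, "range_max": 2, "target": "2 - TET2"},
    {"id": "CMP_expansion", "name": "CMP expansion", "range_min": 0, "range_max": 2, "target": "MYB"},
    {"id": "GMP_expansion", "name": "GMP expansion", "range_min": 0, "range_max": 2, "target": "(2 - NOTCH) + (1 - TET2)"},
    {"id": "GMP_differentiation", "name": "GMP differentiation", "range_min": 0, "range_max": 2, "target": "SPI1 + JAK2 - 1"},
    {"id": "Erythroid_differentiation", "name": "Erythroid differentiation", "range_min": 0, "range_max": 2, "target": "avg(KLF1, GATA1) + STAT5 - 1"},
    {"id": "MEP_expansion", "name": "MEP expansion", "range_min": 0, "range_max": 2, "target": "STAT5"}
  ],
  "edges": [
    {"source": "JAK2", "target": "STAT5", "sign": "activator"},
    {"source": "JAK2", "target": "MAPK", "sign": "activator"},
    {"source": "MAPK", "target": "ITCH", "sign": "activator"},
    {"source": "ITCH", "target": "NOTCH", "sign": "inhibitor"},
    {"source": "NOTCH", "target": "GMP_expansion", "sign": "inhibitor"},
    {"source": "TET2", "target": "GMP_expansion", "sign": "inhibitor"},
    {"source": "STAT5", "target": "HOXA9", "sign": "activator"},
    {"source": "TET2", "target": "HOXA9", "sign": "activator"},
    {"source": "HOXA9", "target": "HOXA9", "sign": "activator"},
    {"source": "HOXA9", "target": "RUNX1", "sign": "activator"},
    {"source": "RUNX1", "target": "SPI1", "sign": "activator"},
    {"source": "GATA1", "target": "SPI1", "sign": "inhibitor"},
    {"source": "RUNX1", "target": "GATA1", "sign": "activator"},
    {"source": "STAT5", "target": "GATA1", "sign": "activator"},
    {"source": "SPI1", "target": "GATA1", "sign": "inhibitor"},
    {"source": "TET2", "target": "KLF1", "sign": "activator"},
    {"source": "GATA1", "target": "KLF1", "sign": "activator"},
    {"source": "SPI1", "target": "MYB", "sign": "inhibitor"},
    {"source": "GATA1", "target": "MYB", "sign": "inhibitor"},
    {"source": "GATA1", "target": "MYC", "sign": "inhibitor"},
    {"source": "MYB", "target": "CMP_expansion", "sign": "activator"},
    {"source": "TET2", "target": "SC_self_renewal", "sign": "inhibitor"},
    {"source": "SPI1", "target": "GMP_differentiation", "sign": "activator"},
    {"source": "JAK2", "target": "GMP_differentiation", "sign": "activator"},
    {"source": "KLF1", "target": "Erythroid_differentiation", "sign": "activator"},
    {"source": "GATA1", "target": "Erythroid_differentiation", "sign": "activator"},
    {"source": "STAT5", "target": "Erythroid_differentiation", "sign": "activator"},
    {"source": "STAT5", "target": "MEP_expansion", "sign": "activator"}
  ]
}
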