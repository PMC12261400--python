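{
  "name": "breast",
  "notes": [
    "Breast-cancer cell-type hierarchy: 9 major, 13 minor and 34 finest-level types.",
    "Transcription ambiguity: the printed per-type results list the monocyte",
    "lineage as a single row, yet the stated counts (34 leaves; 11 of 13 minor",
    "types subdivided) require Monocyte to carry two children. They are named",
    "here by the standard CD14/CD16 monocyte split used by the DISCO atlas.",
    "Minor types that are not subdivided (NK cell, Proliferation T/NK) stand",
    "for themselves at the finer levels, so they appear in several level lists",
    "without being duplicated as tree nodes."
  ],
  "tree": [
    {"name": "B cell", "children": [
      {"name": "IgA plasma cell"},
      {"name": "IgG plasma cell"},
      {"name": "other B cells"}
    ]},
    {"name": "Endothelial cell", "children": [
      {"name": "Arterial EC"},
      {"name": "Capillary EC"},
      {"name": "Lymphatic EC"},
      {"name": "Venous EC"}
    ]},
    {"name": "Epithelial cell", "children": [
      {"name": "Breast basal cell"},
      {"name": "Breast cancer specific luminal cell"},
      {"name": "Breast cancer specific proliferation luminal cell"},
      {"name": "Luminal progenitor"},
      {"name": "TGM2 luminal cell"},
      {"name": "TNBC-specific epithelial cell"}
    ]},
    {"name": "Fibroblast", "children": [
      {"name": "CFD fibroblast"},
      {"name": "CXCL1/2/3 fibroblast"},
      {"name": "other Fibroblasts"}
    ]},
    {"name": "Myeloid cell", "children": [
      {"name": "Dendritic cell", "children": [
        {"name": "cDC2"},
        {"name": "mregDC"},
        {"name": "pDC"}
      ]},
      {"name": "Granulocyte", "children": [
        {"name": "Mast cell"}
      ]},
      {"name": "Macrophages", "children": [
        {"name": "Macrophage"},
        {"name": "Proliferation macrophage"}
      ]},
      {"name": "Monocyte", "children": [
        {"name": "CD14 monocyte"},
        {"name": "CD16 monocyte"}
      ]}
    ]},
    {"name": "NK cell"},
    {"name": "Perivascular cell", "children": [
      {"name": "Pericyte"},
      {"name": "Smooth muscle cell"}
    ]},
    {"name": "Proliferation T/NK"},
    {"name": "T cell", "children": [
      {"name": "CD4 T cell", "children": [
        {"name": "INF responsed T"},
        {"name": "Tfh"},
        {"name": "Treg"}
      ]},
      {"name": "CD8 T cell", "children": [
        {"name": "CXCL13 exhausted CD8 T"},
        {"name": "GZMH CD8 T"},
        {"name": "GZMK CD8 T"}
      ]}
    ]}
  ],
  "levels": [
    {"name": "major", "nodes": [
      "B cell", "Endothelial cell", "Epithelial cell", "Fibroblast",
      "Myeloid cell", "NK cell", "Perivascular cell", "Proliferation T/NK",
      "T cell"
    ]},
    {"name": "minor", "nodes": [
      "B cell", "Endothelial cell", "Epithelial cell", "Fibroblast",
      "Dendritic cell", "Granulocyte", "Macrophages", "Monocyte",
      "NK cell", "Perivascular cell", "Proliferation T/NK",
      "CD4 T cell", "CD8 T cell"
    ]},
    {"name": "sub_minor", "nodes": [
      "IgA plasma cell", "IgG plasma cell", "other B cells",
      "Arterial EC", "Capillary EC", "Lymphatic EC", "Venous EC",
      "Breast basal cell", "Breast cancer specific luminal cell",
      "Breast cancer specific proliferation luminal cell",
      "Luminal progenitor", "TGM2 luminal cell",
      "TNBC-specific epithelial cell",
      "CFD fibroblast", "CXCL1/2/3 fibroblast", "other Fibroblasts",
      "cDC2", "mregDC", "pDC",
      "Mast cell",
      "Macrophage", "Proliferation macrophage",
      "CD14 monocyte", "CD16 monocyte",
      "NK cell",
      "Pericyte", "Smooth muscle cell",
      "Proliferation T/NK",
      "INF responsed T", "Tfh", "Treg",
      "CXCL13 exhausted CD8 T", "GZMH CD8 T", "GZMK CD8 T"
    ]}
  ]
}
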