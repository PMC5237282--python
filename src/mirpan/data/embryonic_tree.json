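{
  "nodes": {
    "Root": {"parent": null, "stage": 0},
    "Endoderm": {"parent": "Root", "stage": 1},
    "Mesoderm": {"parent": "Root", "stage": 1},
    "Ectoderm": {"parent": "Root", "stage": 1},
    "Gut Tube": {"parent": "Endoderm", "stage": 2},
    "Lateral Plate Mesoderm": {"parent": "Mesoderm", "stage": 2},
    "Intermediate Mesoderm": {"parent": "Mesoderm", "stage": 2},
    "Neural Ectoderm/Neural Tube": {"parent": "Ectoderm", "stage": 2},
    "Neural Crest": {"parent": "Ectoderm", "stage": 2},
    "Surface Ectoderm": {"parent": "Ectoderm", "stage": 2},
    "Thymus": {"parent": "Gut Tube", "stage": 3},
    "Lung": {"parent": "Gut Tube", "stage": 3},
    "Pancreas": {"parent": "Gut Tube", "stage": 3},
    "GI tract": {"parent": "Gut Tube", "stage": 3},
    "Liver": {"parent": "Gut Tube", "stage": 3},
    "Thyroid": {"parent": "Gut Tube", "stage": 3},
    "Adipose": {"parent": "Lateral Plate Mesoderm", "stage": 3},
    "Lymph": {"parent": "Lateral Plate Mesoderm", "stage": 3},
    "Heart": {"parent": "Lateral Plate Mesoderm", "stage": 3},
    "Reproductive": {"parent": "Intermediate Mesoderm", "stage": 3},
    "Urinary": {"parent": "Intermediate Mesoderm", "stage": 3},
    "Kidney": {"parent": "Intermediate Mesoderm", "stage": 3},
    "Brain": {"parent": "Neural Ectoderm/Neural Tube", "stage": 3},
    "Peripheral Nervous System": {"parent": "Neural Crest", "stage": 3},
    "Epidermis": {"parent": "Surface Ectoderm", "stage": 3},
    "THYM": {"parent": "Thymus", "stage": 4},
    "LUSC": {"parent": "Lung", "stage": 4},
    "PAAD": {"parent": "Pancreas", "stage": 4},
    "CHOL": {"parent": "GI tract", "stage": 4},
    "ESCA": {"parent": "GI tract", "stage": 4},
    "STAD": {"parent": "GI tract", "stage": 4},
    "LIHC": {"parent": "Liver", "stage": 4},
    "THCA": {"parent": "Thyroid", "stage": 4},
    "ACC": {"parent": "Adipose", "stage": 4},
    "DLBC": {"parent": "Lymph", "stage": 4},
    "MESO": {"parent": "Heart", "stage": 4},
    "CESC": {"parent": "Reproductive", "stage": 4},
    "OV": {"parent": "Reproductive", "stage": 4},
    "TGCT": {"parent": "Reproductive", "stage": 4},
    "UCS": {"parent": "Urinary", "stage": 4},
    "KICH": {"parent": "Kidney", "stage": 4},
    "KIRP": {"parent": "Kidney", "stage": 4},
    "LGG": {"parent": "Brain", "stage": 4},
    "PCPG": {"parent": "Peripheral Nervous System", "stage": 4},
    "SKCM": {"parent": "Epidermis", "stage": 4},
    "UVM": {"parent": "Epidermis", "stage": 4}
  },
  "leaf_assignment": {
    "THYM": "THYM", "LUSC": "LUSC", "PAAD": "PAAD", "CHOL": "CHOL",
    "ESCA": "ESCA", "STAD": "STAD", "LIHC": "LIHC", "THCA": "THCA",
    "ACC": "ACC", "DLBC": "DLBC", "MESO": "MESO", "CESC": "CESC",
    "OV": "OV", "TGCT": "TGCT", "UCS": "UCS", "KICH": "KICH",
    "KIRP": "KIRP", "LGG": "LGG", "PCPG": "PCPG", "SKCM": "SKCM",
    "UVM": "UVM"
  }
}
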