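{
  "GO:0005737": "cytoplasm",
  "GO:0005783": "er",
  "GO:0005788": "er",
  "GO:0005789": "er",
  "GO:0005793": "er",
  "GO:0005615": "extracellular",
  "GO:0005794": "golgi",
  "GO:0005796": "golgi",
  "GO:0000139": "golgi",
  "GO:0005739": "mitochondrion",
  "GO:0005740": "mitochondrion",
  "GO:0005743": "mitochondrion",
  "GO:0005758": "mitochondrion",
  "GO:0005759": "mitochondrion",
  "GO:0031966": "mitochondrion",
  "GO:0005741": "mitochondrion",
  "GO:0005886": "cell_membrane",
  "GO:0005618": "cell_wall",
  "GO:0005634": "nucleus",
  "GO:0009536": "plastid",
  "GO:0009528": "plastid",
  "GO:0005777": "peroxisome",
  "GO:0005778": "peroxisome",
  "GO:0005773": "vacuole",
  "GO:0005774": "vacuole",
  "GO:0016020": "cell_membrane",
  "GO:0009507": "plastid"
}
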