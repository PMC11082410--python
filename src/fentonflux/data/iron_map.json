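{
  "name": "cytosolic iron / ROS map",
  "description": "Factor-graph map of cytosolic iron handling and the reactive-oxygen pools feeding the cytosolic Fenton reaction (O2.- + H2O2 -> .OH + OH- + O2, Fe2+ catalysed). 15 reaction modules: 3 sources of cytosolic Fe2+, 4 sinks of cytosolic Fe2+, ferritin storage of the Fe3+ product, and 7 superoxide/peroxide source-sink modules. Gene memberships are representative HGNC symbols per branch and are meant to be edited; every computation reads membership from this file.",
  "metabolites": [
    "cytosolic Fe2+",
    "cytosolic Fe3+",
    "superoxide",
    "hydrogen peroxide",
    "hydroxyl radical",
    "hydroxide",
    "stored Fe3+ (ferritin)",
    "heme",
    "Fe-S cluster",
    "exported Fe2+",
    "O2"
  ],
  "balanced_set": [
    "cytosolic Fe2+",
    "cytosolic Fe3+",
    "superoxide",
    "hydrogen peroxide"
  ],
  "modules": [
    {
      "name": "Ferrous ion import",
      "genes": ["SLC11A2", "SLC39A14", "SLC39A8"],
      "consumes": [],
      "produces": ["cytosolic Fe2+"],
      "direction_note": "Fe2+ source: divalent metal transporters"
    },
    {
      "name": "Ferric ion import and reduction",
      "genes": ["TF", "TFRC", "STEAP3"],
      "consumes": [],
      "produces": ["cytosolic Fe2+"],
      "direction_note": "Fe2+ source: transferrin cycle + endosomal ferrireductase"
    },
    {
      "name": "Heme import and reduction",
      "genes": ["SLC48A1", "HMOX1", "HMOX2"],
      "consumes": [],
      "produces": ["cytosolic Fe2+"],
      "direction_note": "Fe2+ source: heme uptake and oxygenase-mediated iron release"
    },
    {
      "name": "Fe-S cluster synthesis",
      "genes": ["NFS1", "ISCU", "FXN", "GLRX5"],
      "consumes": ["cytosolic Fe2+"],
      "produces": ["Fe-S cluster"],
      "direction_note": "Fe2+ sink: mitochondrial iron-sulfur cluster assembly"
    },
    {
      "name": "Heme synthesis",
      "genes": ["ALAS1", "ALAD", "PPOX", "FECH"],
      "consumes": ["cytosolic Fe2+"],
      "produces": ["heme"],
      "direction_note": "Fe2+ sink: mitochondrial heme biosynthesis (ferrochelatase)"
    },
    {
      "name": "Fe2+ export",
      "genes": ["SLC40A1", "HEPH", "CP"],
      "consumes": ["cytosolic Fe2+"],
      "produces": ["exported Fe2+"],
      "direction_note": "Fe2+ sink: ferroportin-mediated efflux"
    },
    {
      "name": "Fenton reaction",
      "genes": ["NCOA4", "PCBP1", "PCBP2"],
      "consumes": ["cytosolic Fe2+", "superoxide", "hydrogen peroxide"],
      "produces": ["cytosolic Fe3+", "hydroxyl radical", "hydroxide", "O2"],
      "direction_note": "Fe2+ sink: labile-pool iron oxidised while catalysing O2.- + H2O2 -> .OH + OH- + O2; representative labile-iron-pool chaperone/marker genes"
    },
    {
      "name": "Ferritin synthesis",
      "genes": ["FTH1", "FTL"],
      "consumes": ["cytosolic Fe3+"],
      "produces": ["stored Fe3+ (ferritin)"],
      "direction_note": "Fe3+ sink: storage of the oxidised iron produced by the Fenton reaction"
    },
    {
      "name": "NADPH oxidase superoxide production",
      "genes": ["NOX1", "CYBB", "NOX4", "CYBA"],
      "consumes": [],
      "produces": ["superoxide"],
      "direction_note": "O2.- source: membrane NADPH oxidase complex"
    },
    {
      "name": "Mitochondrial superoxide leak",
      "genes": ["NDUFS1", "NDUFS2", "UQCRC1", "UQCRC2"],
      "consumes": [],
      "produces": ["superoxide"],
      "direction_note": "O2.- source: electron-transport-chain leakage"
    },
    {
      "name": "Superoxide dismutation",
      "genes": ["SOD1", "SOD2"],
      "consumes": ["superoxide"],
      "produces": ["hydrogen peroxide"],
      "direction_note": "O2.- sink / H2O2 source: superoxide dismutases"
    },
    {
      "name": "Peroxisomal oxidase H2O2 production",
      "genes": ["ACOX1", "ACOX2", "DAO", "HAO1"],
      "consumes": [],
      "produces": ["hydrogen peroxide"],
      "direction_note": "H2O2 source: peroxisomal oxidases"
    },
    {
      "name": "Catalase H2O2 decomposition",
      "genes": ["CAT"],
      "consumes": ["hydrogen peroxide"],
      "produces": [],
      "direction_note": "H2O2 sink: catalase"
    },
    {
      "name": "Glutathione peroxidase H2O2 reduction",
      "genes": ["GPX1", "GPX2", "GPX4"],
      "consumes": ["hydrogen peroxide"],
      "produces": [],
      "direction_note": "H2O2 sink: glutathione peroxidases"
    },
    {
      "name": "Peroxiredoxin H2O2 reduction",
      "genes": ["PRDX1", "PRDX2", "PRDX3", "PRDX6"],
      "consumes": ["hydrogen peroxide"],
      "produces": [],
      "direction_note": "H2O2 sink: peroxiredoxins"
    }
  ]
}
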