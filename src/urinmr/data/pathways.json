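{
  "description": "Synthetic toy pathway library for urinary metabolites. Pathway names follow common human metabolic pathways but compound sets and connectivity are simplified stand-ins, not a snapshot of any curated database.",
  "pathways": [
    {
      "id": "pw_phe",
      "name": "Phenylalanine metabolism",
      "compounds": ["l-phenylalanine", "phenylpyruvate", "phenylacetic acid", "phenylacetylglutamine", "l-tyrosine", "hippurate", "benzoate"],
      "edges": [["l-phenylalanine", "phenylpyruvate"], ["phenylpyruvate", "phenylacetic acid"], ["phenylacetic acid", "phenylacetylglutamine"], ["l-phenylalanine", "l-tyrosine"], ["benzoate", "hippurate"], ["phenylpyruvate", "benzoate"]]
    },
    {
      "id": "pw_tyr",
      "name": "Tyrosine metabolism",
      "compounds": ["l-tyrosine", "l-dopa", "dopamine", "homovanillate", "4-hydroxy-3-methoxymandelate", "norepinephrine", "epinephrine", "4-hydroxyphenylpyruvate", "homogentisate"],
      "edges": [["l-tyrosine", "l-dopa"], ["l-dopa", "dopamine"], ["dopamine", "homovanillate"], ["dopamine", "norepinephrine"], ["norepinephrine", "epinephrine"], ["norepinephrine", "4-hydroxy-3-methoxymandelate"], ["epinephrine", "4-hydroxy-3-methoxymandelate"], ["l-tyrosine", "4-hydroxyphenylpyruvate"], ["4-hydroxyphenylpyruvate", "homogentisate"]]
    },
    {
      "id": "pw_purine",
      "name": "Purine metabolism",
      "compounds": ["atp", "adp", "amp", "adenosine", "inosine", "deoxyinosine", "hypoxanthine", "xanthine", "urate", "guanosine"],
      "edges": [["atp", "adp"], ["adp", "amp"], ["amp", "adenosine"], ["adenosine", "inosine"], ["inosine", "hypoxanthine"], ["deoxyinosine", "hypoxanthine"], ["hypoxanthine", "xanthine"], ["xanthine", "urate"], ["guanosine", "xanthine"]]
    },
    {
      "id": "pw_gpl",
      "name": "Glycerophospholipid metabolism",
      "compounds": ["phosphatidylcholine", "phosphatidylethanolamine", "ethanolamine", "choline", "acetylcholine", "glycerophosphocholine", "sn-glycero-3-phosphoethanolamine"],
      "edges": [["phosphatidylcholine", "glycerophosphocholine"], ["glycerophosphocholine", "choline"], ["choline", "acetylcholine"], ["phosphatidylethanolamine", "sn-glycero-3-phosphoethanolamine"], ["sn-glycero-3-phosphoethanolamine", "ethanolamine"], ["ethanolamine", "phosphatidylethanolamine"], ["choline", "phosphatidylcholine"]]
    },
    {
      "id": "pw_aaa_biosyn",
      "name": "Phenylalanine, tyrosine and tryptophan biosynthesis",
      "compounds": ["chorismate", "prephenate", "phenylpyruvate", "l-phenylalanine", "4-hydroxyphenylpyruvate", "l-tyrosine", "anthranilate", "l-tryptophan"],
      "edges": [["chorismate", "prephenate"], ["prephenate", "phenylpyruvate"], ["phenylpyruvate", "l-phenylalanine"], ["prephenate", "4-hydroxyphenylpyruvate"], ["4-hydroxyphenylpyruvate", "l-tyrosine"], ["chorismate", "anthranilate"], ["anthranilate", "l-tryptophan"]]
    },
    {
      "id": "pw_pyrimidine",
      "name": "Pyrimidine metabolism",
      "compounds": ["uridine", "pseudouridine", "uracil", "cytidine", "thymidine", "beta-alanine", "dihydrouracil"],
      "edges": [["uridine", "uracil"], ["uridine", "pseudouridine"], ["cytidine", "uridine"], ["uracil", "dihydrouracil"], ["dihydrouracil", "beta-alanine"], ["thymidine", "uracil"]]
    },
    {
      "id": "pw_ala",
      "name": "Alanine, aspartate and glutamate metabolism",
      "compounds": ["alanine", "pyruvate", "l-aspartate", "l-glutamate", "l-glutamine", "2-oxoglutarate", "2-aminobutyrate"],
      "edges": [["alanine", "pyruvate"], ["l-aspartate", "l-glutamate"], ["l-glutamate", "l-glutamine"], ["l-glutamate", "2-oxoglutarate"], ["pyruvate", "l-aspartate"], ["2-oxoglutarate", "2-aminobutyrate"]]
    },
    {
      "id": "pw_his",
      "name": "Histidine metabolism",
      "compounds": ["l-histidine", "histamine", "carnosine", "anserine", "urocanate", "imidazole-4-acetate"],
      "edges": [["l-histidine", "histamine"], ["l-histidine", "carnosine"], ["carnosine", "anserine"], ["l-histidine", "urocanate"], ["histamine", "imidazole-4-acetate"]]
    },
    {
      "id": "pw_tca",
      "name": "Citrate cycle",
      "compounds": ["citrate", "cis-aconitate", "isocitrate", "2-oxoglutarate", "succinate", "fumarate", "malate", "oxaloacetate"],
      "edges": [["citrate", "cis-aconitate"], ["cis-aconitate", "isocitrate"], ["isocitrate", "2-oxoglutarate"], ["2-oxoglutarate", "succinate"], ["succinate", "fumarate"], ["fumarate", "malate"], ["malate", "oxaloacetate"], ["oxaloacetate", "citrate"]]
    },
    {
      "id": "pw_gly",
      "name": "Glycolysis and gluconeogenesis",
      "compounds": ["glucose", "glucose-6-phosphate", "fructose-6-phosphate", "pyruvate", "lactate", "acetate"],
      "edges": [["glucose", "glucose-6-phosphate"], ["glucose-6-phosphate", "fructose-6-phosphate"], ["fructose-6-phosphate", "pyruvate"], ["pyruvate", "lactate"], ["pyruvate", "acetate"]]
    }
  ],
  "synonyms": {
    "vanillylmandelate": "4-hydroxy-3-methoxymandelate",
    "vma": "4-hydroxy-3-methoxymandelate",
    "homovanillic acid": "homovanillate",
    "hva": "homovanillate",
    "tyrosine": "l-tyrosine",
    "phenylalanine": "l-phenylalanine",
    "phenylacetate": "phenylacetic acid",
    "l-alanine": "alanine"
  }
}
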