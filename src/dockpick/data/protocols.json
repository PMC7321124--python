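{
  "comment": "Default docking-protocol registry: 14 search-algorithm/scoring-function pairings from six engines. Row order of every label matrix and prediction follows this list.",
  "protocols": [
    "autodock-ls",
    "autodock-lga",
    "autodock-ga",
    "glide-sp",
    "gold-asp",
    "gold-chemscore",
    "gold-goldscore",
    "gold-plp",
    "plants-chemplp",
    "plants-plp",
    "plants-plp95",
    "rdock-std",
    "rdock-solv",
    "vina-std"
  ]
}
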