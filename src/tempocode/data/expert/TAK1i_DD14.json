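{
  "elements": [
    "TNF_L",
    "TNF_M",
    "TNF_H",
    "LPS_L",
    "LPS_M",
    "LPS_H",
    "CpG_L",
    "CpG_M",
    "CpG_H",
    "PolyIC_L",
    "PolyIC_M",
    "PolyIC_H",
    "Pam3CSK_L",
    "Pam3CSK_M",
    "Pam3CSK_H"
  ],
  "clusters": [
    [
      "CpG_H",
      "CpG_L",
      "CpG_M",
      "LPS_H",
      "LPS_L",
      "LPS_M",
      "Pam3CSK_H",
      "Pam3CSK_L",
      "Pam3CSK_M",
      "PolyIC_H",
      "PolyIC_L",
      "PolyIC_M",
      "TNF_H",
      "TNF_L",
      "TNF_M"
    ]
  ],
  "nonresponder_cluster": 0
}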