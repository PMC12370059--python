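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
      "TNF_M"
    ],
    [
      "TNF_H"
    ],
    [
      "LPS_M"
    ],
    [
      "LPS_H"
    ],
    [
      "CpG_M"
    ],
    [
      "CpG_H",
      "Pam3CSK_H"
    ],
    [
      "PolyIC_L"
    ],
    [
      "PolyIC_M"
    ],
    [
      "PolyIC_H"
    ],
    [
      "Pam3CSK_M"
    ],
    [
      "CpG_L",
      "LPS_L",
      "Pam3CSK_L",
      "TNF_L"
    ]
  ],
  "nonresponder_cluster": 10
}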