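[
  {
    "marker_id": "P190",
    "sequence": "LPPHPGHPGYINFSYEK",
    "phospho_position": 14,
    "parent_accession": "AMELX_P190_SYN",
    "parent_products": ["amelogenin P190 splice variant and its N-terminal cleavage products"]
  },
  {
    "marker_id": "P173_LRAP",
    "sequence": "MPLPPHPGHPGYINFSYEVLTPLK",
    "phospho_position": 16,
    "parent_accession": "AMELX_P173_SYN",
    "parent_products": ["amelogenin P173 and LRAP and their N-terminal processing products (e.g. TRAP, P148, P62/3, P40)"]
  },
  {
    "marker_id": "AMBN_N",
    "sequence": "QPGTPGVASLSLETMR",
    "phospho_position": 11,
    "parent_accession": "AMBN_SYN",
    "parent_products": ["ameloblastin 15 and 17 kDa N-terminal cleavage products"]
  },
  {
    "marker_id": "ENAM_32k",
    "sequence": "GYHGFGGRPPYYSEEMFEQDFEKPK",
    "phospho_position": 13,
    "parent_accession": "ENAM_SYN",
    "parent_products": ["enamelin 89, 142, 155 and 32 kDa cleavage products"]
  }
]
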