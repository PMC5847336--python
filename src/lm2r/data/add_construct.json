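{
  "name": "add140",
  "numbering_offset": -14,
  "probed_region": [
    5,
    145
  ],
  "reference_loops": [
    [
      -2,
      -1,
      0,
      1,
      2
    ],
    [
      150,
      151,
      152,
      153,
      154
    ]
  ],
  "helices": {
    "P1": [
      [
        19,
        77
      ],
      [
        20,
        76
      ]
    ],
    "P2": [
      [
        29,
        41
      ],
      [
        30,
        40
      ]
    ],
    "P4B": [
      [
        82,
        116
      ],
      [
        83,
        115
      ]
    ]
  },
  "lock_mutants": {
    "lock-P1": "A19U-U20A-A76U-U77A",
    "lock-P4B": "U82A-C83G-G115C-A116U",
    "MutP2": "A29C-A30G-U40C-U41G"
  },
  "note": "Helix registries list only the base pairs implied by the published lock and stabilizer mutant designs; full helix endpoints must be supplied by the user."
}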