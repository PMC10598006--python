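{
  "label free sample": ["label free sample"],
  "TMT6plex": ["TMT126", "TMT127", "TMT128", "TMT129", "TMT130", "TMT131"],
  "TMT10plex": [
    "TMT126", "TMT127N", "TMT127C", "TMT128N", "TMT128C",
    "TMT129N", "TMT129C", "TMT130N", "TMT130C", "TMT131"
  ],
  "TMT11plex": [
    "TMT126", "TMT127N", "TMT127C", "TMT128N", "TMT128C",
    "TMT129N", "TMT129C", "TMT130N", "TMT130C", "TMT131", "TMT131C"
  ],
  "TMT16plex": [
    "TMT126", "TMT127N", "TMT127C", "TMT128N", "TMT128C",
    "TMT129N", "TMT129C", "TMT130N", "TMT130C", "TMT131N",
    "TMT131C", "TMT132N", "TMT132C", "TMT133N", "TMT133C", "TMT134N"
  ],
  "SILAC light/heavy": ["SILAC light", "SILAC heavy"],
  "iTRAQ4plex": ["iTRAQ114", "iTRAQ115", "iTRAQ116", "iTRAQ117"],
  "iTRAQ8plex": [
    "iTRAQ113", "iTRAQ114", "iTRAQ115", "iTRAQ116",
    "iTRAQ117", "iTRAQ118", "iTRAQ119", "iTRAQ121"
  ]
}
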