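{
  "characteristics[organism]": "taxonomy",
  "characteristics[organism part]": "anatomy",
  "characteristics[cell type]": "anatomy",
  "characteristics[disease]": "disease",
  "comment[instrument]": "instrument",
  "comment[cleavage agent details]": "protease",
  "comment[modification parameters]": "modification",
  "comment[label]": "label"
}
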