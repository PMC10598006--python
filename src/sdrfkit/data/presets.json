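{
  "metaproteomics": [
    "characteristics[environmental material]",
    "characteristics[biome]",
    "comment[metagenome accession]",
    "comment[assembly strategy]"
  ]
}
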