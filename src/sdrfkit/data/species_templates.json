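{
  "default": [
    "source name",
    "characteristics[organism]",
    "characteristics[organism part]",
    "characteristics[disease]",
    "characteristics[cell type]",
    "technology type",
    "assay name",
    "comment[fraction identifier]",
    "comment[label]",
    "comment[data file]",
    "comment[instrument]",
    "comment[cleavage agent details]",
    "comment[modification parameters]"
  ],
  "human": [
    "source name",
    "characteristics[organism]",
    "characteristics[organism part]",
    "characteristics[disease]",
    "characteristics[cell type]",
    "characteristics[ancestry category]",
    "characteristics[age]",
    "characteristics[sex]",
    "technology type",
    "assay name",
    "comment[fraction identifier]",
    "comment[label]",
    "comment[data file]",
    "comment[instrument]",
    "comment[cleavage agent details]",
    "comment[modification parameters]"
  ],
  "cell-lines": [
    "source name",
    "characteristics[organism]",
    "characteristics[organism part]",
    "characteristics[disease]",
    "characteristics[cell type]",
    "characteristics[cell line]",
    "technology type",
    "assay name",
    "comment[fraction identifier]",
    "comment[label]",
    "comment[data file]",
    "comment[instrument]",
    "comment[cleavage agent details]",
    "comment[modification parameters]"
  ],
  "plants": [
    "source name",
    "characteristics[organism]",
    "characteristics[organism part]",
    "characteristics[disease]",
    "characteristics[cell type]",
    "technology type",
    "assay name",
    "comment[fraction identifier]",
    "comment[label]",
    "comment[data file]",
    "comment[instrument]",
    "comment[cleavage agent details]",
    "comment[modification parameters]"
  ],
  "vertebrates": [
    "source name",
    "characteristics[organism]",
    "characteristics[organism part]",
    "characteristics[disease]",
    "characteristics[cell type]",
    "characteristics[developmental stage]",
    "technology type",
    "assay name",
    "comment[fraction identifier]",
    "comment[label]",
    "comment[data file]",
    "comment[instrument]",
    "comment[cleavage agent details]",
    "comment[modification parameters]"
  ],
  "invertebrates": [
    "source name",
    "characteristics[organism]",
    "characteristics[organism part]",
    "characteristics[disease]",
    "characteristics[cell type]",
    "characteristics[developmental stage]",
    "technology type",
    "assay name",
    "comment[fraction identifier]",
    "comment[label]",
    "comment[data file]",
    "comment[instrument]",
    "comment[cleavage agent details]",
    "comment[modification parameters]"
  ]
}
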