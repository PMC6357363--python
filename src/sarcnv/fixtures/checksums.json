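{
  "gene_panel.tsv": "edc2aa275b4b3f882005766ee0e086e33fe8ebcd078e05b3367b4af7927bc3f9",
  "cell_lines.tsv": "b7d20219b71f0240132f88d508cda6bdef2c6af2c57ae3174f59f70124c0d130",
  "cohorts.tsv": "d875b0bf59bd50643090461e2a5ffff05ead6e6dbafed359c6a739c9b0f337f2"
}
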