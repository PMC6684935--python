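# Demo pipeline: small synthetic study, completes in well under a minute.
#   phylomatrix run --config examples/demo.yaml --out-dir demo_out
out_dir: demo_out
seed: 5
simulation:
  n_taxa: 12
  n_genes: 30
occupancy_threshold: 0.5
recoding_scheme: dayhoff6
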