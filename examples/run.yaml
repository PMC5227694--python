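# Full synthetic run: every stage on simulated data.
simulate:
  n_proteins: 200
  structures: true
n_samples: 10000
seed: 7
out_dir: demo_out
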