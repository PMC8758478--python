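# Desk-scale preset: runs in minutes on one CPU.
seed: 1
output_dir: lfapp_out_desk
transcriptomics:
  simulate:
    n_genes: 2000
    n_case: 60
    n_control: 60
    de_fraction: 0.17
    n_batches: 3
  boruta:
    max_runs: 15
    n_trees: 150
biophysics:
  scan_mode: direct-sw
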