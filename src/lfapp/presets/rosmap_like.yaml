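# Cohort-scale preset mirroring the published analysis dimensions
# (589 samples, 23,056 genes). Cluster-scale: hours of compute.
seed: 1
output_dir: lfapp_out_rosmap_like
transcriptomics:
  simulate:
    n_genes: 23056
    n_case: 280
    n_control: 309
    de_fraction: 0.17
    n_batches: 6
  boruta:
    max_runs: 10000
    n_trees: 500
biophysics:
  scan_mode: simulate-scans
  n_radial: 400
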