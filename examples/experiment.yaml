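# Minimal end-to-end experiment: hidden-size family on Ising patches
# at two lattice temperatures.  Run with:  rbmtherm run --config examples/experiment.yaml
data:
  source: ising
  temperatures: [2.5, 3.5]
  lattice_side: 10
  n_lattice_samples: 20000
  burn_in: 1000
  thin: 100
  method: swendsen-wang
  patch_pixel_count: 13
  n_patches: 20000
  heldout_fraction: 0.2
  seed: 1
model:
  hidden_sizes: [5, 10, 20, 35, 60]
  schedule: [0.2, 0.1, 0.05, 0.01, 0.005, 0.001]
  epochs_per_stage: 6
  minibatch: 8
  seed: 2
analysis:
  n_bins: 10
  ev_source: free_energy
  conditional_samples: 2000
  gibbs_chains: 500
  gibbs_keep: 100000
  gibbs_thin: 2
  gibbs_burn_in: 300
  run_fim_sweep: false
  seed: 3
output_dir: scratch/experiment
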