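# Baseline NAD(P)H comparison: T24-like cells cultured without collagen
# (free-NAD(P)H fraction a1 = 77%) versus embedded in fibroblast-structured
# collagen (a1 = 83%), identical component lifetimes 0.38 / 2.7 ns.
seed: 11
output_dir: flimcell_run
acquisition:
  repetition_period: 12.5   # ns (80 MHz sync)
  n_bins: 256
  irf_fwhm: 0.2             # ns
  photon_rate: 1.5e5        # photons/s
  collection_time: 60.0     # s
  dark_count_fraction: 0.01
scene:
  n_cells: 5
  n_scenes: 2
  shape: [192, 192]
  nucleus_budget_fraction: 0.4
groups:
  no_collagen:
    channels:
      nadh:
        cytoplasm: {lifetimes: [0.38, 2.7], amplitudes: [0.77, 0.23]}
        nucleus: {lifetimes: [0.38, 2.7], amplitudes: [0.77, 0.23]}
  collagen_fibroblasts:
    channels:
      nadh:
        cytoplasm: {lifetimes: [0.38, 2.7], amplitudes: [0.83, 0.17]}
        nucleus: {lifetimes: [0.38, 2.7], amplitudes: [0.83, 0.17]}
segmentation:
  mode: classical
fitting:
  models: {nadh: biexp}
stats:
  metrics: ["nadh/a1", "nadh/tau_m"]
  compartments: [cytoplasm, nucleus]
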