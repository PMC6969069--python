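# Demonstration run: an siRNA-style silenced condition against its control.
# Two imaging conditions (3 replicates x 3 fields of ~80 cells), a spread
# population pair, a 10-gene CNA matrix and a 300-patient survival cohort.
seed: 7

imaging:
  pixel_size: 0.5
  min_nuclei_per_condition: 200

field:
  image_size: [900, 900]
  pixel_size: 0.5
  n_cells: 80
  apoptotic_fraction: 0.03
  border_fraction: 0.05

conditions:
  - label: siControl
    control: true
    mn_rate: 0.02
    n_replicates: 3
    n_fields: 3
  - label: siSMC3-P
    mn_rate: 0.30
    n_replicates: 3
    n_fields: 3

spreads:
  control:
    label: siControl
    n_spreads: 100
    n_replicates: 3
    modal_count: 45
    count_noise: {-1: 0.05, 0: 0.9, 1: 0.05}
    defect_rate: 0.05
    mean_defective: 2
  conditions:
    - label: siSMC3-P
      n_spreads: 100
      n_replicates: 3
      modal_count: 45
      count_noise: {-2: 0.1, -1: 0.15, 0: 0.5, 1: 0.15, 2: 0.1}
      tetraploid_fraction: 0.2
      defect_rate: 0.7
      mean_defective: 8
      p_moderate: 0.5
      p_severe: 0.15

cna:
  n_genes: 10
  n_samples: 300
  deletion_prob: 0.259   # 1 - (1-p)^10 ~ 0.95 cumulative

survival:
  n: 300
  cutpoint_percentile: 50
  hazard_ratio: 2.5
  censor_rate: 0.2
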