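# Desk-scale demonstration pipeline: 580 µm tissue block, 29 µm elements,
# default-calibration angioarchitecture, 90 µm cortical indentation, 2 ms.
seed: 1
domain_size: [580.0, 580.0, 580.0]
image:
  spacing: 5.8
meshing:
  coarsen: 5
  smooth_iterations: 2
scenario:
  impactor_radius: 150.0
  impact_depth: 90.0
  impact_velocity: 1000.0
  dwell_time: 1.0
  retract: true
  total_sim_time: 2.0
  edge_fillet: 80.0
analysis:
  n_bootstrap: 500
output:
  directory: runs/demo
  write_fields: false
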