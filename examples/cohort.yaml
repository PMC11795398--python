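# Synthetic two-group cohort: two acquisition batches with a planted
# +0.10 display-scale shift on CD5/CD4 in batch2, and a 1.5x enrichment
# of the CD8 T-cell population in group B.
seed: 11
output_dir: flowpheno_run
simulate:
  enabled: true
  samples_per_group: {A: 12, B: 12}
  events_per_sample: 500.0
  batch_shifts:
    batch1: {}
    batch2: {CD5: 0.10, CD4: 0.10}
  group_effects:
    B: {CD8_T: 1.5}
downsample:
  cap: 5000
cluster:
  resolution: 0.3
annotate:
  rules:
    - cell_type: CD4 T cells
      predicates:
        - {marker: CD5, field: mean, op: ">=", threshold: 0.5}
        - {marker: CD4, field: mean, op: ">=", threshold: 0.5}
    - cell_type: CD8 T cells
      predicates:
        - {marker: CD5, field: mean, op: ">=", threshold: 0.5}
        - {marker: CD8, field: mean, op: ">=", threshold: 0.5}
    - cell_type: B cells
      predicates:
        - {marker: CD21, field: mean, op: ">=", threshold: 0.5}
        - {marker: MHCII, field: mean, op: ">=", threshold: 0.5}
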