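# Full-pipeline configuration for `ipahes run-all --config examples/run.yaml`.
# With no `inputs:` block the pipeline generates its own seeded synthetic
# dataset; point `inputs.episodes` / `inputs.demographics` / `inputs.registry`
# at CSVs (and the selection/anchors blocks at code-list files) to run on
# real extracts.
seed: 5
out_dir: pipeline_out
synth:
  n_cases: 60
  n_per_violator: 10
  n_validation_cases: 80
selection:
  earliest_diagnosis: 2012-04-01
  hcru_cap: 250
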