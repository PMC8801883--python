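# Demo run: full pipeline on the default study conditions.
#   kernelset all --config examples/demo_config.yaml
seed: 42
outdir: runs/demo
stages: [simulate, allometry, growth, fit, traits, anova, correlate]
shading: {}
density: {}
log_level: INFO
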