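# Small end-to-end demo: synthetic dataset -> split -> RF13 -> evaluation.
# Run with:  grainpigment run --config examples/demo.yaml
seed: 1
out_dir: runs/demo
generator:
  classes: {NP: 4, A: 4, M: 4, AM: 4}
  hulled_fraction: 0.5
  replicates: 3
  image_size: 96
split:
  fractions: [0.6, 0.2, 0.2]
classifier:
  model_kind: rf13   # rf13 | cnn | unet_classhead | unet_classsegment
evaluation:
  split: test
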