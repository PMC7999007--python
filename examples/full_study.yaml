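# The full rotation study at desk scale: 21 labels per plane on the
# -5..5 deg half-degree grid. Train with: craniomsp train-rot --n-bases 8
grid: [-5.0, 5.0, 0.5]
classifier:
  n_labels: 21
  input_side: 32
  Min Batch Size: 24
  epochs: 16
segmentation:
  Optimizer: adam
  Encoder Depth: 4
  Filter Size: 5
  Number of First Encoder Filter: 6
  Patch Per Image: 4
  Initial Learning Rate: 0.01
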