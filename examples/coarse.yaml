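# Demonstration configuration: the full 21-label half-degree grid on a
# reduced number of phantom bases (pass --n-bases 2 for a quick run;
# the full study uses 8 bases).
grid: [-5.0, 5.0, 0.5]
classifier:
  n_labels: 21
  input_side: 32
  Min Batch Size: 24
  epochs: 20
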