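network:
  embed_dim: 32
  encoder_layers: 1
  decoder_layers: 1
  attention_heads: 2
  seed: 0
training:
  learning_rate: 0.001
  batch_size: 50
  train_passes: 2
  seed: 0
play:
  rounds: 30
  n_targets: 50
  target_length: 20
  target_seed: 11
  seed: 0
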