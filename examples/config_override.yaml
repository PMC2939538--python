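# Example configuration: a smaller rat with a flatter drinking rhythm.
# Any omitted key keeps the reference-rat default; lookup tables are given
# as ordered [x, y] knot lists.
weight: 200
days: 5
seed: 42
drinking:
  unregulated_amplitude: 0.4
  bout_volume_ml: 0.5
ald_volume_table: [[0.0, 0.0], [0.05, 60.0], [0.12, 200.0]]
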