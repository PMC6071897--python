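{
  "config_hash": "9560d232b608af6e",
  "seed": 2026,
  "n_patients": 200,
  "n_block_groups": 30
}
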