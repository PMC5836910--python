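name: table_uniform
shape: sinc_gaussian_no_lobes
tau_ms: 15.0
gap_ms: 15.0
n_pulses: 50
td_ms:
- 18.0
- 112.0
- 206.0
- 300.0
fixed_block_ms: 6301.0
eta_us: 100.0
snr_ref: 25.0
points:
- offset_hz: 400.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 768.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 1474.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 2828.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 5429.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 10420.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 20000.0
  b1_uT: 4.872972972972973
  flip_deg: 601.0000000000001
- offset_hz: 400.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
- offset_hz: 768.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
- offset_hz: 1474.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
- offset_hz: 2828.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
- offset_hz: 5429.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
- offset_hz: 10420.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
- offset_hz: 20000.0
  b1_uT: 8.91891891891892
  flip_deg: 1099.9999999999998
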