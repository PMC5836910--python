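name: table_optimized
shape: sinc_gaussian_no_lobes
tau_ms: 15.0
gap_ms: 15.0
n_pulses: 25
td_ms:
- 18.0
- 112.0
- 206.0
- 300.0
fixed_block_ms: 6302.000000000001
eta_us: 100.0
snr_ref: 25.0
points:
- offset_hz: 1018.0
  b1_uT: 3.0648648648648646
  flip_deg: 377.99999999999994
- offset_hz: 1031.0
  b1_uT: 3.1054054054054054
  flip_deg: 383.00000000000006
- offset_hz: 1029.0
  b1_uT: 3.1216216216216215
  flip_deg: 385.0
- offset_hz: 1311.0
  b1_uT: 3.186486486486487
  flip_deg: 393.0
- offset_hz: 1706.0
  b1_uT: 3.4540540540540543
  flip_deg: 426.0
- offset_hz: 2102.0
  b1_uT: 3.6972972972972977
  flip_deg: 456.00000000000006
- offset_hz: 13710.0
  b1_uT: 11.57027027027027
  flip_deg: 1427.0000000000002
- offset_hz: 1000.0
  b1_uT: 11.87027027027027
  flip_deg: 1464.0
- offset_hz: 3250.0
  b1_uT: 11.886486486486488
  flip_deg: 1466.0
- offset_hz: 3517.0
  b1_uT: 11.894594594594594
  flip_deg: 1467.0
- offset_hz: 3348.0
  b1_uT: 11.91891891891892
  flip_deg: 1469.9999999999998
- offset_hz: 3283.0
  b1_uT: 11.927027027027027
  flip_deg: 1471.0
- offset_hz: 3420.0
  b1_uT: 11.927027027027027
  flip_deg: 1471.0
- offset_hz: 13985.0
  b1_uT: 11.927027027027027
  flip_deg: 1471.0
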