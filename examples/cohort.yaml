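# Example synthetic-cohort configuration (paper-scale arms, desk-scale
# recordings). Increase duration_s / fs for full-scale signals.
group_sizes: [16, 15, 19]
fs: 512.0
duration_s: 30.0
noise_exponent: 1.0
noise_amplitude_uv: 8.0
oscillators:
  delta: {center_hz: 2.0, bandwidth_hz: 2.0, amplitude_uv: 4.0}
  theta: {center_hz: 6.0, bandwidth_hz: 2.0, amplitude_uv: 3.0}
  alpha: {center_hz: 10.0, bandwidth_hz: 2.0, amplitude_uv: 6.0}
  beta: {center_hz: 20.0, bandwidth_hz: 6.0, amplitude_uv: 2.0}
# visit-2 amplitude multipliers: delta up / alpha down in the CRB_sham arm
effects:
  CRB_sham: {delta: 1.4, alpha: 0.75}
missingness: [2, 1]
seed: 20000523
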