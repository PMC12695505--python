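# Default electrode-to-zone assignment for the 32-channel 10-20 montage.
# Conventional lobe grouping; override with a user file of the same shape.
# whole_scalp is implicit (all electrodes) and need not be listed.
labels:
  - Fp1
  - Fp2
  - F3
  - F4
  - F7
  - F8
  - Fz
  - C3
  - C4
  - Cz
  - P3
  - P4
  - P7
  - P8
  - Pz
  - O1
  - O2
  - Oz
  - FC1
  - FC2
  - FC5
  - FC6
  - CP1
  - CP2
  - CP5
  - CP6
  - T7
  - T8
  - TP9
  - TP10
  - PO9
  - PO10
zones:
  frontal: [Fp1, Fp2, F3, F4, F7, F8, Fz, FC1, FC2, FC5, FC6]
  central: [C3, C4, Cz]
  parietal: [P3, P4, P7, P8, Pz, CP1, CP2, CP5, CP6]
  temporal: [T7, T8, TP9, TP10]
  occipital: [O1, O2, Oz, PO9, PO10]
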