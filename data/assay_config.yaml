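scenario:
  base_k: 0.01
  chis:
  - 0.0
  - 0.125
  - 0.25
  - 0.375
  - 0.5
  - 0.75
  - 1.0
  end_factor: 2.0
  geometry:
    radius: 200.0
    thickness: 3.0
  name: assay
  noise_sd: 0.01
  peak_chi: 0.375
  peak_factor: 10.0
  seed: 2017
  times:
  - 0
  - 2
  - 4
  - 6
  - 8
  - 10
  - 12
  - 14
  - 16
  - 18
  - 20
  - 22
  - 24
  - 26
  - 28
  - 30
  - 32
  - 34
  - 36
  - 38
  - 40
  - 42
  - 44
  - 46
  - 48
  - 50
  - 52
  - 54
  - 56
  - 58
  - 60
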