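# Four distorted-Gaussian populations on a square, 2D benchmark geometry
components:
  - {mean: [300, 300], sd: [130, 130], count: 30000, k1: 0, k2: 1, s: 0.002, truncate: 3.2553}
  - {mean: [720, 300], sd: [130, 130], count: 30000, k1: 0, k2: 1, s: 0.002, truncate: 3.2553}
  - {mean: [300, 720], sd: [130, 130], count: 20000, k1: 0, k2: 1, s: 0.002, truncate: 3.2553}
  - {mean: [720, 720], sd: [130, 130], count: 20000, k1: 0, k2: 1, s: 0.002, truncate: 3.2553}
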