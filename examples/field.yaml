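# FCRF delivery scenario: 50-plant row at 0.6 m spacing.
layout:
  positions: [0.0, 0.6, 1.2, 1.8, 2.4, 3.0, 3.6, 4.2, 4.8, 5.4,
              6.0, 6.6, 7.2, 7.8, 8.4, 9.0, 9.6, 10.2, 10.8, 11.4,
              12.0, 12.6, 13.2, 13.8, 14.4, 15.0, 15.6, 16.2, 16.8, 17.4,
              18.0, 18.6, 19.2, 19.8, 20.4, 21.0, 21.6, 22.2, 22.8, 23.4,
              24.0, 24.6, 25.2, 25.8, 26.4, 27.0, 27.6, 28.2, 28.8, 29.4]
  tolerance: 0.05
timing:
  L1: 1.0        # camera-to-funnel distance (m)
  H1: 1.0        # funnel height (m)
  H2: 0.5095     # whorl height (m) -> ΔH = 0.4905, T2 = 0.316 s
  V1: 0.5        # platform speed (m/s)
  T1: 0.2        # signal delay (s)
detector:
  p_detect: 0.912
noise:
  timing_jitter_sd: 0.057
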