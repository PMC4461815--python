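# Published Gabor filter parameters of the channel-energy observer, one
# entry per texture set.  sigma: envelope width (degrees); freq: spatial
# frequency (cycles/degree); theta: orientation (degrees).
sets:
  1:  {sigma: 0.085, freq: 6.87, theta: 22.5}
  2:  {sigma: 0.085, freq: 6.87, theta: 45.0}
  3:  {sigma: 0.085, freq: 6.87, theta: 45.0}
  4:  {sigma: 0.123, freq: 6.61, theta: 45.0}
  5:  {sigma: 0.123, freq: 6.61, theta: 45.0}
  6:  {sigma: 0.085, freq: 6.87, theta: 45.0}
  7:  {sigma: 0.085, freq: 6.87, theta: 45.0}
  8:  {sigma: 0.085, freq: 6.87, theta: 22.5}
  9:  {sigma: 0.085, freq: 6.87, theta: 45.0}
  10: {sigma: 0.085, freq: 6.87, theta: 45.0}
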