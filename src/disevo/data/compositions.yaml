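# Default region-class amino-acid compositions, version 1.
# "ordered" emulates folded-domain composition (enriched I, L, V, F, W, Y, M);
# "disordered" emulates linker/IDR composition (enriched E, K, S, P, Q, G).
ordered:
  I: 0.11
  L: 0.12
  V: 0.11
  F: 0.08
  W: 0.03
  Y: 0.05
  M: 0.04
  A: 0.10
  G: 0.07
  T: 0.06
  S: 0.05
  C: 0.02
  H: 0.02
  N: 0.03
  Q: 0.03
  D: 0.02
  E: 0.02
  K: 0.02
  R: 0.01
  P: 0.01
disordered:
  E: 0.14
  K: 0.13
  S: 0.12
  P: 0.10
  Q: 0.09
  G: 0.09
  D: 0.06
  R: 0.05
  N: 0.04
  T: 0.04
  A: 0.05
  H: 0.02
  M: 0.01
  I: 0.01
  L: 0.02
  V: 0.02
  F: 0.005
  Y: 0.005
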