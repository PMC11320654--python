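# DP4+ error-model parameters, gas-phase mPW1PW91/6-31+G**//B3LYP/6-31G*
#
# Same layout and provenance caveat as the PCM file: best-effort
# transcription of the published DP4+ parametrization — verify against
# the original tables before production use.
H1:
  scaled:   {mu: 0.0,    sigma: 0.112, nu: 6.0}
  unscaled: {mu: -0.077, sigma: 0.232, nu: 4.8}
  sigma_ref: 31.89
C13:
  scaled:   {mu: 0.0,    sigma: 1.88,  nu: 7.9}
  unscaled: {mu: -2.00,  sigma: 3.43,  nu: 6.2}
  sigma_ref: 188.61
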