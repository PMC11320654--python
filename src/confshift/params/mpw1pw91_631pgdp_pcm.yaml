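# DP4+ error-model parameters, PCM(chloroform)/mPW1PW91/6-31+G**//B3LYP/6-31G*
#
# Location-scale Student-t parameters (mu, sigma in ppm; nu = degrees of
# freedom) for scaled and unscaled shift errors, and the TMS reference
# shieldings (ppm) at the same level. Transcribed best-effort from the
# published DP4+ parametrization (Grimblat, Zanardi & Sarotti,
# J. Org. Chem. 2015, 80, 12526); VERIFY against that publication's
# tables for your exact level of theory before production use, and edit
# this file (or pass --params) to override.
H1:
  scaled:   {mu: 0.0,    sigma: 0.108, nu: 6.2}
  unscaled: {mu: -0.051, sigma: 0.211, nu: 4.5}
  sigma_ref: 31.85
C13:
  scaled:   {mu: 0.0,    sigma: 1.78,  nu: 8.4}
  unscaled: {mu: -1.05,  sigma: 2.94,  nu: 6.4}
  sigma_ref: 186.52
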