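# Default initial-profile marginals emulating the 2011 National Youth
# Tobacco Survey high-school population (synthetic emulation: survey
# microdata is not bundled; values are set from published summary
# statistics and the package's documented scoring conventions).
#
# Smoking state: 15.8% current (30-day) conventional-cigarette use and
# 1.5% current e-cigarette use, with 1.0% dual use counted in both.
stateProbs:
  NONE: 0.837
  CC_ONLY: 0.148
  EC_ONLY: 0.005
  DUAL: 0.010

# "How many of your four closest friends smoke cigarettes?" — default is
# Binomial(4, 0.158), i.e. friend smoking consistent with independent
# mixing at the population prevalence.
friendCountProbs: [0.502631, 0.377271, 0.106191, 0.013284, 0.000623]

# Openness items ("If one of your friends offered you a cigarette, would
# you smoke it?" / "Do you think you will smoke a cigarette anytime during
# the next year?"): 4-point responses scored {0, 1/3, 2/3, 1} and the two
# items averaged. Item response probabilities: definitely not, probably
# not, probably yes, definitely yes.
opennessCCDist:
  kind: survey_items
  itemProbs: [0.55, 0.18, 0.13, 0.14]
opennessECDist:
  kind: survey_items
  itemProbs: [0.55, 0.18, 0.13, 0.14]

# 30-day use-day fraction given current use of a product: bucket midpoints
# (days / 30) with typical youth occasional-to-daily mix.
freqUseDist:
  kind: discrete
  values: [0.05, 0.133, 0.25, 0.483, 0.817, 1.0]
  probs: [0.15, 0.10, 0.10, 0.15, 0.15, 0.35]

# Integer age 13..19 (high-school population).
ageProbs: [0.02, 0.20, 0.21, 0.21, 0.20, 0.14, 0.02]

# Gaussian rank-correlation copula coupling smoking state, number of
# smoking friends and openness while preserving the marginals above.
# Survey data consistently show smokers report more smoking friends and
# higher openness/susceptibility; set to null for independent draws.
copula:
  rhoStateFriends: 0.55
  rhoStateOpenness: 0.90
  rhoFriendsOpenness: 0.30
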