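# Baseline utility parameters calibrated against the 2011-2014 NYTS
# prevalence trajectory and the 2014 scenario responses (docs/methods.md).
# thetaCC/thetaEC/crossover are baseline scenario values (all zero).
muCC: -10.731
muEC: -7.422
eta: 11.732
phi: 1.017
wPeer: 3.974
wSoc: 3.48
alphaPeerMix: 0.407
gammaOpen: 2.996
thetaCC: 0.0
thetaEC: 0.0
crossover: 0.0
kappaDual: -1.75
tasteScale: 1.0
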