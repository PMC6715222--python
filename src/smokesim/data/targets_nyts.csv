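# Yearly observed prevalence of current (30-day) conventional-cigarette
# (CC) and e-cigarette (EC) use among US high-school students, National
# Youth Tobacco Survey 2011-2014. Point estimates transcribed from the
# published CDC survey reports; 95% CI bounds are approximations at the
# published precision (the survey microdata is not bundled).
year,product,prev,ciLow,ciHigh
2011,CC,0.158,0.139,0.179
2011,EC,0.015,0.012,0.019
2012,CC,0.140,0.123,0.159
2012,EC,0.028,0.023,0.035
2013,CC,0.127,0.108,0.149
2013,EC,0.045,0.037,0.055
2014,CC,0.092,0.078,0.108
2014,EC,0.134,0.119,0.151
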