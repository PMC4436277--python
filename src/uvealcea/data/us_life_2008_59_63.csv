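# Annual probability of death from all causes, 2008 US life tables,
# total population (National Vital Statistics), ages 59-63.
age,qx
59,0.008480
60,0.009155
61,0.009822
62,0.010474
63,0.011132
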