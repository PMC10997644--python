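# Informative-prior hyperparameters obtained from the nine-interval
# elicitation spec (gamma shape/rate per component, Dirichlet exponents).
a1 = 0.9379
b1 = 0.8332
a2 = 0.7530
b2 = 0.6344
a3 = 0.5335
b3 = 0.4339
a = 2.4950
b = 2.5060
c = 2.0200
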