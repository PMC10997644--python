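# Censored-sample sufficient statistics for the Kevlar 373/epoxy fatigue
# lifetimes, entered on the negative-log scale with termination time 3.4.
n = 76
log_inv_t = 3.4
u1 = 22
u2 = 22
u3 = 21
S1 = 31.2771
S2 = 32.3513
S3 = 30.1508
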