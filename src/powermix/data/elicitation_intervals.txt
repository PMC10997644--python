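# Elicitation targets: z1 z2 target_probability
0.05 0.15 0.08
0.15 0.25 0.07
0.25 0.35 0.06
0.35 0.45 0.06
0.45 0.55 0.065
0.55 0.65 0.07
0.65 0.75 0.08
0.75 0.85 0.09
0.85 0.95 0.10
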