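system	tap5	tap10	tap20
best_team	0.3297	0.3538	0.3535
composite_N0	0.3527	0.4241	0.4435
composite_N5	0.3594	0.4465	0.4522
composite_N10	0.3614	0.4318	0.4454
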