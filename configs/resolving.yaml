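# A resolving configuration: baseline constants with easier macrophage
# recruitment (alpha_mr lowered from 0.4 to 0.25) on a 50x50 domain.
alpha_mr: 0.25
grid_shape: [50, 50]
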