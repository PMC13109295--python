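# Small rhombus leaf for the shoot preset.
angle: 40
step: 1
axiom: A
A -> { . +(25) F(0.7) . -(50) F(0.7) . -(130) F(0.7) . }
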