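# Flat rhombus leaf blade: a closed polygon from base to tip and back.
# One derivation step rewrites A into the outline; F lengths set blade size.
angle: 40
step: 1
axiom: A
A -> { . +(22) F(1.2) . -(44) F(1.2) . -(136) F(1.2) . }
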