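# Stochastic shoot: a main axis that either branches (carrying leafy
# branchlets) or elongates, so leaf counts vary from seed to seed.
angle: 25
step: 0.7
axiom: !(0.08) A(6)
A(n) : n > 0 -> (0.65) F [ +(35) &(25) B(2) ] [ -(35) ^(20) B(2) ] /(137.5) A(n-1) | (0.35) F /(90) A(n-1)
B(n) : n > 0 -> F(0.5) [ +(45) L ] B(n-1)
B(n) : n == 0 -> L
sub L = shoot_leaf.lsys @ 1 class=leaf
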