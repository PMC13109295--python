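# Deterministic rosette: 8 leaves around the axis at the golden divergence
# angle, each pitched a little differently. One leaf placeholder L is spliced
# per unrolling of A(n), so the derived string carries exactly 8 leaves.
angle: 137.5
step: 1
axiom: A(8)
A(n) : n > 0 -> [ &(42 + 3*n) L ] /(137.5) A(n-1)
sub L = rosette_leaf.lsys @ 1 class=leaf
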