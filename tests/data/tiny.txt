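# hand-written 3-vertex skeleton: two stem vertices and one branch vertex
pitch 0.5
v 0 0.0 0.0 0.0 2.0
v 1 0.0 0.0 -2.0 2.0
v 2 3.0 0.0 -2.0 0.8
e 0 1
e 1 2
stem 0 1
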