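# five-leaf tree and its one-contraction coarsening
a b | c d e
a b e | c d
a | b c d e
a b c d | e
a b c e | d
a b d e | c
a c d e | b

a b | c d e
a | b c d e
a b c d | e
a b c e | d
a b d e | c
a c d e | b
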