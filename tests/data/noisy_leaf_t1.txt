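a b c d | e f g h
a b c d e | f g h
a b c d e f | g h
a b e f g h | c d
a e f g h | b c d
a | b c d e f g h
a b c d e f g | h
a b c d e f h | g
a b c d e g h | f
a b c d f g h | e
a b c e f g h | d
a b d e f g h | c
a c d e f g h | b
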