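a b c d | e f g h i
a b c d e | f g h i
a b c d e f | g h i
a b c d e f g | h i
a b e f g h i | c d
a e f g h i | b c d
a | b c d e f g h i
a b c d e f g h | i
a b c d e f g i | h
a b c d e f h i | g
a b c d e g h i | f
a b c d f g h i | e
a b c e f g h i | d
a b d e f g h i | c
a c d e f g h i | b

a b c | d e f g h j
a b c d | e f g h j
a b c d e | f g h j
a b c d e f | g h j
a b c d e f g | h j
a d e f g h j | b c
a | b c d e f g h j
a b c d e f g h | j
a b c d e f g j | h
a b c d e f h j | g
a b c d e g h j | f
a b c d f g h j | e
a b c e f g h j | d
a b d e f g h j | c
a c d e f g h j | b
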