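a b | c e
a | b c e
a b c | e
a b e | c
a c e | b
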