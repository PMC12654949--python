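BEGIN_base-pair
     1_20, A:     1 G-C    20 A: +/+ cis         XIX
     4_33, A:     4 C-G    33 B: +/+ cis         XIX
END_base-pair
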