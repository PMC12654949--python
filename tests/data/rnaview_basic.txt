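BEGIN_base-pair
     1_20, A:     1 G-C    20 A: +/+ cis         XIX
     2_19, A:     2 A-U    19 A: +/+ cis         XX
     3_18, A:     3 G-U    18 A: W/W cis         XXVIII
     5_15, A:     5 A-G    15 A: H/W tran        n/a
     8_9, A:     8 A-G     9 A:      stacked
END_base-pair
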