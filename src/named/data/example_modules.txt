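ENTRY       M00175
NAME        Nitrogen fixation, nitrogen => ammonia
DEFINITION  K02588+K02586+K02591-K00531
///
ENTRY       M00531
NAME        Assimilatory nitrate reduction, nitrate => ammonia
DEFINITION  (K00367,K10534,K00372-K00360) (K00366,K17877,K26139)
///
ENTRY       M00529
NAME        Denitrification, nitrate => nitrogen
DEFINITION  (K00370+K00371+K00374,K02567+K02568) (K00368,K15864) (K04561+K02305,K15877) K00376
///
ENTRY       M00176
NAME        Assimilatory sulfate reduction, sulfate => H2S
DEFINITION  (K13811,K00958+K00860,K00955+K00957,K00956+K00957+K00860) (K00390,K05907) (K00380+K00381,K00392)
///
ENTRY       M00596
NAME        Dissimilatory sulfate reduction, sulfate => H2S
DEFINITION  K00958 K00394+K00395 K11180+K11181
///
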