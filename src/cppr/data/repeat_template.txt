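# 35-aa consensus PPR repeat. Positions 5 and 35 are the specificity slots
# and are written here as their poly(A)-design residues (T and N); they are
# substituted per target base at design time.
VVTYTTLISGLGKAGRLEEALELFEEMKEKGIKPN
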