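# Base-recognition code for consensus PPR repeats.
# Columns: amino acid at repeat position 5, amino acid at repeat position 35,
# recognised base (T stands for both T and U).
# Extra rows may be appended to extend the code; the first row for each base
# is treated as the canonical design pair.
aa5	aa35	base
T	N	A
N	S	C
T	D	G
N	D	T
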