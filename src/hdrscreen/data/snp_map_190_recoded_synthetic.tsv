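offset	side	ref_base	donor_base
-850	five_prime	G	A
-725	five_prime	T	G
-600	five_prime	A	C
-450	five_prime	A	G
-319	five_prime	A	T
-220	five_prime	C	A
-150	five_prime	A	G
-94	five_prime	T	A
-60	five_prime	C	A
16	three_prime	T	A
75	three_prime	A	C
130	three_prime	A	T
220	three_prime	T	A
310	three_prime	C	A
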