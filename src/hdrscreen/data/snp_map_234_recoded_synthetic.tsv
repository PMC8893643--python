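offset	side	ref_base	donor_base
-319	five_prime	C	G
-260	five_prime	T	A
-190	five_prime	A	T
-140	five_prime	G	T
-94	five_prime	C	A
-60	five_prime	C	G
-30	five_prime	A	T
52	three_prime	A	T
88	three_prime	A	T
149	three_prime	C	G
210	three_prime	T	C
280	three_prime	T	G
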