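pos	consensus	A	C	G	T
-2	A	0.79	0.07	0.07	0.07
-1	G	0.07	0.07	0.79	0.07
+1	g	0.07	0.07	0.79	0.07
+2	t	0.07	0.07	0.07	0.79
+3	r	0.43	0.07	0.43	0.07
+4	a	0.79	0.07	0.07	0.07
+5	g	0.07	0.07	0.79	0.07
+6	t	0.07	0.07	0.07	0.79
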