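pos	consensus	A	C	G	T
-14	y	0.07	0.43	0.07	0.43
-13	y	0.07	0.43	0.07	0.43
-12	y	0.07	0.43	0.07	0.43
-11	y	0.07	0.43	0.07	0.43
-10	y	0.07	0.43	0.07	0.43
-9	y	0.07	0.43	0.07	0.43
-8	y	0.07	0.43	0.07	0.43
-7	y	0.07	0.43	0.07	0.43
-6	y	0.07	0.43	0.07	0.43
-5	y	0.07	0.43	0.07	0.43
-4	n	0.25	0.25	0.25	0.25
-3	y	0.07	0.43	0.07	0.43
-2	a	0.79	0.07	0.07	0.07
-1	g	0.07	0.07	0.79	0.07
+1	G	0.07	0.07	0.79	0.07
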