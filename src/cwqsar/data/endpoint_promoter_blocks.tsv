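endpoint_1	endpoint_2	attribute	e1_r1	e1_r2	e1_r3	e2_r1	e2_r2	e2_r3
mutagenicity	anticancer	1...........	+	+	+	+	+	+
mutagenicity	anticancer	c...2.......	+	+	+	+	+	+
mutagenicity	anticancer	c...(.......	+	+	+	+	+	+
mutagenicity	anticancer	3...........	+	+	+	+	+	+
mutagenicity	anticancer	C...........	+	+	+	+	+	+
mutagenicity	anticancer	1...(.......	+	+	+	+	+	+
mutagenicity	anticancer	C...1.......	+	+	+	+	+	+
mutagenicity	anticancer	C...3.......	+	+	+	+	+	+
mutagenicity	anticancer	Cl..(.......	+	+	+	+	+	+
mutagenicity	anticancer	Cl..........	+	+	+	+	+	+
mutagenicity	anticancer	c...........	+	+	+	-	-	-
mutagenicity	anticancer	O...........	+	+	+	-	-	-
mutagenicity	anticancer	O...(.......	+	+	+	-	-	-
mutagenicity	anticancer	N...(.......	-	-	-	+	+	+
mutagenicity	anticancer	++++N---O===	-	-	-	+	+	+
mutagenicity	anticancer	NOSP11000000	-	-	-	+	+	+
mutagenicity	anticancer	C...(.......	-	-	-	+	+	+
mutagenicity	anticancer	C...C.......	-	-	-	+	+	+
mutagenicity	bbb	1...........	+	+	+	+	+	+
mutagenicity	bbb	BOND00000000	+	+	+	+	+	+
mutagenicity	bbb	HALO00000000	+	+	+	+	+	+
mutagenicity	bbb	NOSP10000000	+	+	+	+	+	+
mutagenicity	bbb	1...(.......	+	+	+	+	+	+
mutagenicity	bbb	++++CL--N===	+	+	+	+	+	+
mutagenicity	bbb	-...........	+	+	+	+	+	+
mutagenicity	bbb	=...(.......	+	+	+	+	+	+
mutagenicity	bbb	C...1.......	+	+	+	+	+	+
mutagenicity	bbb	BOND10000000	+	+	+	+	+	+
mutagenicity	bbb	Cl..(.......	+	+	+	+	+	+
mutagenicity	bbb	Cl..........	+	+	+	+	+	+
mutagenicity	bbb	N...+.......	+	+	+	+	+	+
mutagenicity	bbb	N...........	-	-	-	-	-	-
mutagenicity	bbb	O...........	+	+	+	-	-	-
mutagenicity	bbb	O...(.......	+	+	+	-	-	-
mutagenicity	bbb	N...1.......	+	+	+	-	-	-
mutagenicity	bbb	[...+.......	+	+	+	-	-	-
mutagenicity	bbb	NOSP11000000	-	-	-	+	+	+
mutagenicity	bbb	C...(.......	-	-	-	+	+	+
mutagenicity	bbb	C...C.......	-	-	-	+	+	+
bbb	anticancer	C...C.......	+	+	+	+	+	+
bbb	anticancer	C...(.......	+	+	+	+	+	+
bbb	anticancer	1...........	+	+	+	+	+	+
bbb	anticancer	C...1.......	+	+	+	+	+	+
bbb	anticancer	C...=.......	+	+	+	+	+	+
bbb	anticancer	++++N---B2==	+	+	+	+	+	+
bbb	anticancer	C...2.......	+	+	+	+	+	+
bbb	anticancer	NOSP11000000	+	+	+	+	+	+
bbb	anticancer	1...(.......	+	+	+	+	+	+
bbb	anticancer	O...C.......	+	+	+	+	+	+
bbb	anticancer	2...(.......	+	+	+	+	+	+
bbb	anticancer	4...........	+	+	+	+	+	+
bbb	anticancer	Cl..........	+	+	+	+	+	+
bbb	anticancer	Cl..(.......	+	+	+	+	+	+
bbb	anticancer	++++S---B2==	+	+	+	+	+	+
bbb	anticancer	HALO01000000	+	+	+	+	+	+
bbb	anticancer	++++F---B2==	+	+	+	+	+	+
bbb	anticancer	++++F---N===	+	+	+	+	+	+
bbb	anticancer	HALO10000000	+	+	+	+	+	+
bbb	anticancer	N...4.......	+	+	+	+	+	+
bbb	anticancer	++++CL--S===	+	+	+	+	+	+
bbb	anticancer	(...........	-	-	-	-	-	-
bbb	anticancer	O...........	-	-	-	-	-	-
bbb	anticancer	O...(.......	-	-	-	-	-	-
bbb	anticancer	5...........	-	-	-	-	-	-
bbb	anticancer	C...5.......	-	-	-	-	-	-
bbb	anticancer	++++Cl--B2==	+	+	+	-	-	-
bbb	anticancer	F...(.......	+	+	+	-	-	-
bbb	anticancer	++++F---Cl==	+	+	+	-	-	-
bbb	anticancer	++++O---B2==	-	-	-	+	+	+
bbb	anticancer	2...........	-	-	-	+	+	+
bbb	anticancer	=...2.......	-	-	-	+	+	+
bbb	anticancer	3...(.......	-	-	-	+	+	+
bbb	anticancer	++++O---S===	-	-	-	+	+	+
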