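attribute	source	mr_s1r1	mr_s1r2	mr_s1r3	mr_s2r1	mr_s2r2	mr_s2r3	mr_s3r1	mr_s3r2	mr_s3r3	total_mr	fr_s1r1	fr_s1r2	fr_s1r3	fr_s2r1	fr_s2r2	fr_s2r3	fr_s3r1	fr_s3r2	fr_s3r3	total_fr
1...(.......	smiles	0	0	0	0	0	0	0	0	0	0	1	1	1	1	0	1	1	0	1	7
2...(.......	smiles	1	1	1	0	0	0	1	1	1	6	0	0	0	0	0	0	0	0	0	0
2...1.......	smiles	1	1	0	0	0	1	1	1	0	5	0	0	0	0	0	0	0	0	0	0
C...1.......	smiles	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	2
C...2.......	smiles	0	1	0	1	1	0	0	1	0	4	0	0	0	0	0	0	0	0	0	0
N...=.......	smiles	1	0	0	0	1	1	1	0	0	4	0	0	0	0	0	0	0	0	0	0
N...1.......	smiles	0	0	0	1	1	1	0	0	0	3	0	0	0	0	0	0	0	0	0	0
HALO00000000	smiles	1	1	1	1	1	1	1	1	1	9	0	0	0	0	0	0	0	0	0	0
BOND00000000	smiles	1	0	1	0	0	0	1	0	1	4	1	1	1	1	1	1	1	1	1	9
BOND10000000	smiles	0	0	0	0	0	0	0	0	0	0	1	1	0	1	1	1	0	0	0	5
BOND10100000	smiles	1	1	1	1	1	1	1	1	1	9	0	0	0	0	0	0	0	0	0	0
C5......0...	graph	0	0	0	1	0	1	0	0	0	2	1	0	0	1	1	1	0	0	0	4
C6......0...	graph	1	1	1	1	1	1	1	1	1	9	1	1	1	1	1	1	1	1	0	8
NNC-C...101.	graph	1	1	1	1	1	1	1	1	1	9	0	0	0	0	0	0	1	1	0	2
NNC-C...110.	graph	0	0	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	0	1	5
NNC-C...211.	graph	1	1	1	1	1	1	1	1	1	9	1	1	1	1	1	1	1	1	1	9
NNC-C...303.	graph	1	1	1	1	0	0	1	1	1	7	0	0	0	0	0	0	0	0	0	0
NNC-C...321.	graph	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	0	7
NNC-O...101.	graph	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	2
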