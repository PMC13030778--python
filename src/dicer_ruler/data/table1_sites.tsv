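# Functional-site residues of insect Dicer-2 orthologs: RNase III A/B catalytic
# centers and PAZ 3'/5' terminal-nucleotide-binding pockets, with author residue
# numbering from the D. melanogaster crystal structure (PDB 7v6c) and homology
# models of the other species.
# Assumption: chain IDs are not part of the published residue lists; chain "A"
# is used throughout.
# "?" in residue_number/expected_aa marks a residue that could not be assigned
# in the ortholog alignment (includes the uncertain B. terrestris THR769).
structure_id	site_name	chain_id	residue_number	expected_aa
dmel	RIII_A	A	1213	E
dmel	RIII_A	A	1217	D
dmel	RIII_A	A	1368	D
dmel	RIII_A	A	1371	E
dmel	RIII_B	A	1472	E
dmel	RIII_B	A	1476	D
dmel	RIII_B	A	1614	D
dmel	RIII_B	A	1617	E
dmel	pocket_3prime	A	886	Y
dmel	pocket_3prime	A	887	A
dmel	pocket_3prime	A	888	N
dmel	pocket_3prime	A	910	K
dmel	pocket_3prime	A	920	F
dmel	pocket_3prime	A	921	T
dmel	pocket_3prime	A	924	K
dmel	pocket_3prime	A	925	Y
dmel	pocket_3prime	A	971	V
dmel	pocket_5prime	A	740	Y
dmel	pocket_5prime	A	743	H
dmel	pocket_5prime	A	744	M
dmel	pocket_5prime	A	773	N
dmel	pocket_5prime	A	774	Q
dmel	pocket_5prime	A	943	R
dmel	pocket_5prime	A	944	D
dmel	pocket_5prime	A	945	L
dmel	pocket_5prime	A	946	T
tcas	RIII_A	A	1165	E
tcas	RIII_A	A	1169	D
tcas	RIII_A	A	1308	D
tcas	RIII_A	A	1311	E
tcas	RIII_B	A	1410	E
tcas	RIII_B	A	1414	D
tcas	RIII_B	A	1515	D
tcas	RIII_B	A	1518	E
tcas	pocket_3prime	A	865	Y
tcas	pocket_3prime	A	866	R
tcas	pocket_3prime	A	867	S
tcas	pocket_3prime	A	?	?
tcas	pocket_3prime	A	898	Y
tcas	pocket_3prime	A	899	Y
tcas	pocket_3prime	A	902	K
tcas	pocket_3prime	A	903	H
tcas	pocket_3prime	A	947	E
tcas	pocket_5prime	A	721	N
tcas	pocket_5prime	A	724	T
tcas	pocket_5prime	A	725	I
tcas	pocket_5prime	A	754	S
tcas	pocket_5prime	A	755	N
tcas	pocket_5prime	A	918	K
tcas	pocket_5prime	A	919	G
tcas	pocket_5prime	A	920	L
tcas	pocket_5prime	A	921	S
bter	RIII_A	A	1016	E
bter	RIII_A	A	1020	D
bter	RIII_A	A	1160	D
bter	RIII_A	A	1163	E
bter	RIII_B	A	1258	E
bter	RIII_B	A	1262	D
bter	RIII_B	A	1364	D
bter	RIII_B	A	1367	E
bter	pocket_3prime	A	746	Y
bter	pocket_3prime	A	747	R
bter	pocket_3prime	A	748	A
bter	pocket_3prime	A	?	?
bter	pocket_3prime	A	778	Y
bter	pocket_3prime	A	779	Y
bter	pocket_3prime	A	782	K
bter	pocket_3prime	A	783	H
bter	pocket_3prime	A	819	E
bter	pocket_5prime	A	611	R
bter	pocket_5prime	A	614	T
bter	pocket_5prime	A	615	F
bter	pocket_5prime	A	644	R
bter	pocket_5prime	A	645	V
bter	pocket_5prime	A	798	K
bter	pocket_5prime	A	799	S
bter	pocket_5prime	A	800	I
bter	pocket_5prime	A	801	S
lmig	RIII_A	A	1032	E
lmig	RIII_A	A	1036	D
lmig	RIII_A	A	1167	D
lmig	RIII_A	A	1170	E
lmig	RIII_B	A	1270	E
lmig	RIII_B	A	1274	D
lmig	RIII_B	A	1377	D
lmig	RIII_B	A	1380	E
lmig	pocket_3prime	A	858	R
lmig	pocket_3prime	A	859	K
lmig	pocket_3prime	A	860	F
lmig	pocket_3prime	A	?	?
lmig	pocket_3prime	A	889	Q
lmig	pocket_3prime	A	890	N
lmig	pocket_3prime	A	893	I
lmig	pocket_3prime	A	894	D
lmig	pocket_3prime	A	934	I
lmig	pocket_5prime	A	729	D
lmig	pocket_5prime	A	732	I
lmig	pocket_5prime	A	733	L
lmig	pocket_5prime	A	762	A
lmig	pocket_5prime	A	763	E
lmig	pocket_5prime	A	910	I
lmig	pocket_5prime	A	911	I
lmig	pocket_5prime	A	912	I
lmig	pocket_5prime	A	913	S
tni	RIII_A	A	1615	E
tni	RIII_A	A	1619	D
tni	RIII_A	A	1766	D
tni	RIII_A	A	1769	E
tni	RIII_B	A	1869	E
tni	RIII_B	A	1873	D
tni	RIII_B	A	1975	D
tni	RIII_B	A	1978	E
tni	pocket_3prime	A	1290	Y
tni	pocket_3prime	A	1291	R
tni	pocket_3prime	A	1292	V
tni	pocket_3prime	A	?	?
tni	pocket_3prime	A	1323	Y
tni	pocket_3prime	A	1324	Y
tni	pocket_3prime	A	1327	K
tni	pocket_3prime	A	1328	Y
tni	pocket_3prime	A	1386	E
tni	pocket_5prime	A	1150	R
tni	pocket_5prime	A	1153	A
tni	pocket_5prime	A	1154	L
tni	pocket_5prime	A	1183	T
tni	pocket_5prime	A	1184	V
tni	pocket_5prime	A	1344	R
tni	pocket_5prime	A	1345	N
tni	pocket_5prime	A	1346	I
tni	pocket_5prime	A	1347	S
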