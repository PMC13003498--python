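TITL synthetic-sponge-host
CELL 0.02510   15.2000   11.1000   21.8000   90.000   96.100   90.000
ZERR 1 0 0 0 0 0 0
LATT -1
SYMM -x+1/2,y,-z
SYMM -x,-y,-z
SYMM x+1/2,-y,z
SYMM x+1/2,y+1/2,z+1/2
SYMM -x,y+1/2,-z+1/2
SYMM -x+1/2,-y+1/2,-z+1/2
SYMM x,-y+1/2,z+1/2
SFAC Bi O C
UNIT 1 1 1
FVAR 1.00000
BI1      1   0.104000   0.121000   0.083000   11.00000   0.02000
O1       2   0.148000   0.253000   0.104000   11.00000   0.03000
O2       2   0.021000   0.049000   0.132000   11.00000   0.03000
O1W      2   0.201000   0.047000   0.021000   11.00000   0.04000
C1       3   0.230000   0.310000   0.140000   11.00000   0.04000
Q1   1   0.310000   0.420000   0.250000   11.00000   0.05000   3.42
Q2   1   0.355000   0.530000   0.270000   11.00000   0.05000   2.87
Q3   1   0.290000   0.350000   0.310000   11.00000   0.05000   1.95
HKLF 4
END
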