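peak,wavenumber,vibration,assignment
1,3380,O-H stretching of bonded and non-bonded hydroxyl groups,Included water; lignin
2,2920,Asymmetric C-H stretching,Aliphatic methylene
3,2850,Symmetric C-H stretching,Aliphatic methylene
4,1735,Un-conjugated C=O stretching,Xylan (hemicellulose)
5,1650,O-H bending; conjugated C-O stretching,Absorbed water; carboxylates
6,1600,Aromatic ring vibration; C=C skeletal vibration,Lignin
7,1510,Aromatic ring vibration,Lignin
8,1460,C-H deformation,Lignin; xylan
9,1429,C-H deformation; CH2 scissoring,Lignin; crystalline cellulose
10,1370,Symmetric C-H deformation,Crystalline cellulose; hemicellulose
11,1320,C-H vibration; CH2 wagging,"Cellulose, hemicellulose, lignin"
12,1240,C-O stretching,Xylan (hemicellulose)
13,1160,C-O-C asymmetric stretching,Crystalline cellulose; hemicellulose
14,1111,In-plane ring stretching,Crystalline cellulose
15,1053,C-O stretching,Crystalline cellulose; hemicellulose
16,898,C-O-C stretching,Amorphous cellulose
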