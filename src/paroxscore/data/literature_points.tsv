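gene	families
ATP1A2	21
ATP1A3	26
CACNA1A	14
CACNA1S	0
CHAMP1	6
GFAP	18
HMBS	6
MEFV	2
OTC	54
POGZ	10
POLG	2
PPM1D	8
RYR2	4
SCN4A	0
SCN9A	0
SCN10A	0
SLC2A1	11
TNFRSF1A	0
TRAP1	2
TRPA1	0
TUBB3	9
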