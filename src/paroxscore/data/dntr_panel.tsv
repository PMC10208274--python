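gene	phenotypes
GABBR1
GABBR2
GABRA1
GABRA5
GABRB1
GABRB2
GABRB3
GABRG2
GRIA1
GRIA2
GRIA3
GRIA4
GRIN1
GRINA
GRIN2A
GRIN2B
GRIN2C
GRIN2D
GRM1
GLRA1
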