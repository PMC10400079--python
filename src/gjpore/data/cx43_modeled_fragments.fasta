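>Cx43_res2-105 human connexin-43 (GJA1, UniProt P17302) residues 2-105
GDWSALGKLLDKVQAYSTAGGKVWLSVLFIFRILLLGTAVESAWGDEQSAFRCNTQQPGC
ENVCYDKSFPISHVRFWVLQIIFVSVPTLLYLAHVFYVMRKEEK
>Cx43_res151-235 human connexin-43 (GJA1, UniProt P17302) residues 151-235
LLRTYIISILFKSIFEVAFLLIQWYIYGFSLSAVYTCKRDPCPHQVDCFLSRPTEKTIFI
IFMLVVSLVSLALNIIELFYVFFKG
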