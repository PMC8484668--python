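# Genes treated as missense-constrained (PP2-eligible) in the synthetic demo KB
PTPN11
SLC26A4
KCNQ4
WFS1
ACTG1
CDH23
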