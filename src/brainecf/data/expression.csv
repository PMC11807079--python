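cell_line,level,expression
Caco-2,highest,7.4
Caco-2,average,4.7
Caco-2,lowest,2
LLC-PK1-MDR1,lowest,13.1
LLC-PK1-mdr1a,highest,61
LLC-PK1-mdr1a,average,38.1
LLC-PK1-mdr1a,lowest,15.2
MDCKII-MDR1,highest,10.3
MDCKII-MDR1,average,6.3
MDCKII-MDR1,lowest,2.2
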