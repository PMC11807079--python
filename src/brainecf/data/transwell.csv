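drug,cell_line,papp_ab_inh,er_c,inhibitor,source,note
acetaminophen,Caco-2,31.9,1.0,parental,Kamiya2020,papp_ab_inh assumed equal to papp_ab (not transported by P-gp)
raclopride,Caco-2,73.4,1.1,Zosquidar+KO-143+Benzbromarone,Colclough2024,er_c determined in MDCKI-MDR1 cells
morphine,Caco-2,2.08,1.6,Cyclosporine A,Crowe2002,
morphine,MDCKII-MDR1,2.12,1.3,parental,Verscheijden2021,
morphine,MDCKII-MDR1,1.8,1.3,parental,Feng2008,
morphine,MDCKII-MDR1,4.8,1.9,parental,Garberg2005,
paliperidone,LLC-PK1-mdr1a,14.7,8.1,parental,Inoue2012,
paliperidone,LLC-PK1-MDR1,13.3,5.3,parental,Inoue2012,
paliperidone,MDCKII-MDR1,16.8,3.3,parental,Feng2008,
quinidine,Caco-2,52.0,4.3,GF120918,Korjamo2006,
quinidine,Caco-2,58.9,1.5,Verapamil,Mukkavilli2017,
quinidine,Caco-2,54.5,5.2,GW918,Troutman2003a,
quinidine,LLC-PK1-mdr1a,56.90,16.1,parental,Nicolai2020,
quinidine,LLC-PK1-mdr1a,57.2,32.8,parental,Uchida2011,
quinidine,LLC-PK1-MDR1,15.9,12.9,parental,Nagaya2020,
quinidine,MDCKII-MDR1,9.52,5.9,parental,Bicker2017,
quinidine,MDCKII-MDR1,8.0,7.4,parental,Feng2008,
quinidine,MDCKII-MDR1,36.8,7.3,parental,Troutman2003b,
risperidone,Caco-2,1.56,4.1,Verapamil,Cousein2007,
risperidone,LLC-PK1-mdr1a,15.8,3.6,parental,Inoue2012,
risperidone,LLC-PK1-mdr1a,66.2,2.1,parental,Nicolai2020,
risperidone,LLC-PK1-mdr1a,96.3,10.6,parental,Uchida2011,
risperidone,LLC-PK1-MDR1,14.0,3.4,parental,Inoue2012,
risperidone,LLC-PK1-MDR1,15.6,3.9,parental,Nagaya2014,
risperidone,MDCKII-MDR1,19.8,2.0,parental,Feng2008,
risperidone,MDCKII-MDR1,53.6,1.7,GF120918,MaharDoan2002,
verapamil,LLC-PK1-mdr1a,41.5,2.9,parental,Nicolai2020,
verapamil,LLC-PK1-mdr1a,73.5,13.3,parental,Uchida2011,
verapamil,LLC-PK1-MDR1,22.3,5.4,parental,Nagaya2014,
verapamil,LLC-PK1-MDR1,47.1,2.7,parental,Nicolai2020,
verapamil,MDCKII-MDR1,12.6,2.1,parental,Feng2008,
verapamil,MDCKII-MDR1,44.0,1.74,GF120918,MaharDoan2002,
verapamil,MDCKII-MDR1,28.6,2.65,parental,Troutman2003b,
verapamil,MDCKII-MDR1,30.0,3.10,parental,Garberg2005,
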