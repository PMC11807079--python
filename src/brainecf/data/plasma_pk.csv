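drug,regimen_class,cl_cen,q_cen_per1,q_cen_per2,v_cen,v_per1,v_per2,ka,note
acetaminophen,short,4.71,1.23,1.45,0.727,892,162.5,,source table renders ambiguously; best-effort transcription
raclopride,short,47.7,16.55,6.88,360,345,7.5,,source table renders ambiguously; best-effort transcription
morphine,short,22.6,30.8,7.2,152,530,1200,,
paliperidone,short,21.9,5.67,0,253,2981,0,,second peripheral compartment unreadable in source; collapsed to two compartments
quinidine,short,178.3,238,754,1847,335,5063,,source table renders ambiguously; best-effort transcription
risperidone,short,77,0,0,525,0,0,0.03,
paliperidone,continuous,29.2,0,0,2053,0,0,,
quinidine,continuous,250,0,0,7314,0,0,,
risperidone,continuous,370,0,0,3799,0,0,,
verapamil,continuous,72.3,0,0,11700,0,0,,
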