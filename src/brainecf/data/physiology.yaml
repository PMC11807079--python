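# Default rat CNS physiology.  sa_bbb and trans_fraction are the BBB
# surface-area values of the scaling relations; the remaining entries are
# approximate literature values for the adult rat and are config data a
# user can override per run.
sa_bbb: 155.0          # cm^2, BBB surface area
trans_fraction: 0.998  # fraction of sa_bbb available transcellularly
v_mv: 0.06             # mL, brain microvascular volume
v_ecf: 0.29            # mL, brain extracellular fluid volume
v_bc: 0.0044           # mL, brain cell membrane compartment volume
q_cbf: 1.2             # mL/min, cerebral blood flow
q_ecf: 0.0003          # mL/min, brainECF bulk flow (terminal sink)
ph_ecf: 7.3            # brainECF pH
body_weight: 0.25      # kg, typical rat, converts mg/kg doses
pgp_expression_in_vivo: 19.4  # fmol/ug total protein, rat brain microvessels
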