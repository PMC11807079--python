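# Drug physicochemical defaults (approximate literature values; config
# data, user-overridable).  fup: unbound fraction in plasma; pka/species
# drive the unionized fraction for membrane partitioning; cl_bc_in/out
# default to 0 (membrane compartment disabled); observed_kpuu_bbb are the
# literature unbound partition coefficients used for the extent-only
# scaled-plasma comparison.
acetaminophen: {fup: 0.85, pka: 9.4, species: acid}
raclopride: {fup: 0.76, pka: 8.9, species: base}
morphine: {fup: 0.7, pka: 8.2, species: base, observed_kpuu_bbb: 0.23}
paliperidone: {fup: 0.26, pka: 8.8, species: base}
quinidine: {fup: 0.18, pka: 8.6, species: base}
risperidone: {fup: 0.1, pka: 8.2, species: base, observed_kpuu_bbb: 0.147}
verapamil: {fup: 0.06, pka: 8.9, species: base}
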