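# Dosing regimens of the validation studies.  duration: null marks a
# loading dose whose administration time is not reported; it is delivered
# as a zero-order infusion over the configurable loading duration
# (default 1 min, i.e. effectively a bolus).
loading_duration_min: 1.0
regimens:
  acetaminophen:
    short: {route: IV, doses: [{mg_per_kg: 15, start: 0, duration: 10}]}
  raclopride:
    short: {route: IV, doses: [{mg_per_kg: 0.56, start: 0, duration: 10}]}
  morphine:
    short: {route: IV, doses: [{mg_per_kg: 40, start: 0, duration: 10}]}
  paliperidone:
    short: {route: IV, doses: [{mg_per_kg: 0.5, start: 0, duration: 20}]}
    continuous:
      route: IV
      doses:
        - {mg_per_kg: 0.8, start: 0, duration: null}
        - {mg_per_kg: 4, start: 0, duration: 240}
  quinidine:
    short: {route: IV, doses: [{mg_per_kg: 20, start: 0, duration: 10}]}
    continuous:
      route: IV
      doses:
        - {mg_per_kg: 8.0, start: 0, duration: null}
        - {mg_per_kg: 20, start: 0, duration: 240}
  risperidone:
    short: {route: SC, doses: [{mg_per_kg: 3, start: 0, duration: 0}]}
    continuous:
      route: IV
      doses:
        - {mg_per_kg: 0.7, start: 0, duration: null}
        - {mg_per_kg: 4, start: 0, duration: 240}
  verapamil:
    continuous:
      route: IV
      doses:
        - {mg_per_kg: 0.9, start: 0, duration: null}
        - {mg_per_kg: 4, start: 0, duration: 240}
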