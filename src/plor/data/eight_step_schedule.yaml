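# 8-step pause-restart schedule for the pbuE adenine riboswitch template.
# Step 1 uses a high explicit NTP excess to drive initiation; steps 2-8 are
# stoichiometric (1x = segment base counts x DNA concentration).
dna_uM: 5
rnap_uM: 5
steps:
  - included: [A, G, U]
    explicit: {A: 400, G: 600, U: 64}
    condition: {temperature_C: 37, duration_min: 15}
  - included: [A, C, U]
    fold: 1.0
  - included: [A, G, U]
    fold: 1.0
  - included: [A, C, U]
    fold: 1.0
  - included: [A, C, G]
    fold: 1.0
  - included: [A, C, U]
    fold: 1.0
  - included: [A, G, U]
    fold: 1.0
  - included: [A, C, G, U]
    fold: 1.0
    condition: {Mg_mM: 6}
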