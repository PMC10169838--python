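# Cetuximab (anti-EGFR), KD ~0.39 nM.
kf1: 2.8e-5
kf2: 2.3e-4
kf3: 2.3e-4
kf4: 2.8e-5
kr1: 1.0e-6
kr2: 9.0e-5
kr3: 9.0e-5
kr4: 1.0e-6
metadata:
  antibody: Cetuximab
  antigen: EGFR
  source: reconstructed from published SPR kinetics (KD ~0.39 nM) and self-labeling enzyme rate
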