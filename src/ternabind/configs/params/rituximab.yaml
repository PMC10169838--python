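# Rituximab (anti-CD20). CD20 binding is notably weaker than the other
# panel antibodies (KD ~8 nM).
kf1: 2.8e-5
kf2: 2.0e-4
kf3: 2.0e-4
kf4: 2.8e-5
kr1: 1.0e-6
kr2: 1.6e-3
kr3: 1.6e-3
kr4: 1.0e-6
metadata:
  antibody: Rituximab
  antigen: CD20
  source: reconstructed from published SPR kinetics (KD ~8 nM) and self-labeling enzyme rate
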