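# Herceptin / trastuzumab (anti-HER2), KD ~0.44 nM.
kf1: 2.8e-5
kf2: 7.9e-4
kf3: 7.9e-4
kf4: 2.8e-5
kr1: 1.0e-6
kr2: 3.5e-4
kr3: 3.5e-4
kr4: 1.0e-6
metadata:
  antibody: Herceptin
  antigen: HER2
  source: reconstructed from published SPR kinetics (KD ~0.44 nM) and self-labeling enzyme rate
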