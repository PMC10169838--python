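# FMC63 (anti-CD19) adaptor. Reactions 1/4: covalent receptor-tag chemistry
# (second-order labeling rate ~2.8e4 M^-1 s^-1; reverse rate is a small
# placeholder for an effectively irreversible bond). Reactions 2/3: scFv/IgG
# binding kinetics to CD19 from surface plasmon resonance literature.
kf1: 2.8e-5   # nM^-1 s^-1
kf2: 2.2e-4
kf3: 2.2e-4
kf4: 2.8e-5
kr1: 1.0e-6   # s^-1
kr2: 7.2e-5
kr3: 7.2e-5
kr4: 1.0e-6
metadata:
  antibody: FMC63
  antigen: CD19
  source: reconstructed from published SPR kinetics (KD ~0.33 nM) and self-labeling enzyme rate
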