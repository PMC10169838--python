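# Co-incubation design: 1e5 effector cells + 2e5 target cells per well.
# receptors_per_effector is a placeholder (no direct measurement available);
# antigens_per_target is a literature-typical density for the target line.
n_effector_cells: 1.0e+5
n_target_cells: 2.0e+5
receptors_per_effector: 1.0e+5
antigens_per_target: 2.0e+5
volume_ml: 0.2
antibody_mw_g_per_mol: 150000.0
dose_grid_ug_per_ml: {min: 1.0e-4, max: 1.0e+1, n: 60}
t_max_s: 3.0e+7
equilibrium_tolerance: 1.0e-8
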