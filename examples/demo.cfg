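# Demo pipeline configuration: bisubstrate-inhibitor-like kinetics at two
# concentrations and four force biases. Values are JSON; units in key names
# or comments. Runs end to end in well under five minutes on one CPU.
seed = 1
ligand = "AP5A"
concentration_unit = "nM"
concentrations = [100.0, 300.0]
trap_separations = [380.0, 397.0, 412.0, 427.0]
duration_s = 6.0
k_close_per_conc = 0.18
delta_x_close = -0.1
k_open = 1.0
delta_x_open = 1.5
contraction_nm = 1.6
trap_k1 = 0.3
trap_k2 = 0.3
noise_amplitude_nm = 0.4
detect_method = "hmm"
bootstrap = 200
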