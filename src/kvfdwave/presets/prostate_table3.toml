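# Transluminal prostate scenario: 4 mm stiff tumour at the far corner of a
# 20 x 40 mm prostatic domain outside a 3.25 mm lumen, probed by a 700 Hz
# Gaussian monocycle of 0.3 rad and an array of 32 wall receivers.

[geometry]
rd_mm = 20.0
zd_mm = 40.0
ru_mm = 3.25

[discretisation]
dr_um = 150.0
dz_um = 150.0
dt_us = 20.0
t_total_ms = 42.0
t_memory_ms = 1.0
n_pml = 60

[materials]
background = "prostate_normal"

[[materials.inclusions]]
shape = "circle"
center_r_mm = 16.0
center_z_mm = 36.0
diameter_mm = 4.0
material = "prostate_cancer"

[probe]
emitter_z_mm = 1.0
emitter_length_mm = 2.0
frequency_hz = 700.0
amplitude_rad = 0.3
waveform = "gaussian_monocycle"
n_receivers = 32
receiver_spacing_mm = 0.8
receiver_length_mm = 0.5
receiver_start_mm = 3.0

[outputs]
log_level = "info"
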