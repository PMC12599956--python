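# Calibrated simulator parameters (produced by scripts/calibrate.py).
#
# The self-activation landscape is bistable with the unstable point just
# above the initial-condition range (no immediate high-state flips) and a
# shallow escape well, so high-expression excursions arise from chemical
# noise throughout early growth; the timer rate is set slightly below the
# tissue growth rate so mean cell size rises and the commitment window
# closes as the tissue matures.
P_A: 0.4
V_A: 1.6
K_A: 1.15
n_A: 4.0
G_A: 1.0
V_T: 1.0
K_T: 1.1
n_T: 6.0
G_T: 0.3
theta_T: 0.6
P_C: 0.042
theta_CS: 0.5
theta_CD: 1.0
E0: 6.5
c0: 1.0
k_radial: 0.009
k_axial: 0.017
dt: 0.1
t_end: 135.0
t_select: 55.0
dilute_timer: true
n_init_rings: 3
init_cell_size: 1.0
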