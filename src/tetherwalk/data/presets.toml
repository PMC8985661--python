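# Parameter presets for MAP and motor constructs.
#
# Only the FL MAP7 dissociation constant (K_D = 111 nM), the dynein
# half-max inhibition (via n_clear = 8), the 16-nm kinesin step and the
# stepping direction statistics are constrained by measurement; absolute
# exchange rates are not, so k_off defaults to 1 /s and k_on = k_off / K_D.
# p_detach_block is calibrated so the saturating-MAP7 stepping pipeline
# reproduces the measured sideways/backward fractions (see docs/methods.md).

[map.FL_MAP7]
k_on = 0.009009009009009009   # per nM per site per s; K_D = 111 nM
k_off = 1.0
hill_h = 1.0
has_mtbd = true
has_projection = true
tail_weight = 0.5
tail_kd_nM = 2000.0

[map.MTBD_only]
k_on = 0.009009009009009009
k_off = 1.0
hill_h = 1.0
has_mtbd = true
has_projection = false
tail_weight = 0.0

[map.dMTBD]
k_on = 0.0
k_off = 1.0
has_mtbd = false
has_projection = true
tail_weight = 0.5
tail_kd_nM = 2000.0

[map.MAP7_N]
k_on = 0.009009009009009009
k_off = 1.0
has_mtbd = true
has_projection = false
tail_weight = 0.5
tail_kd_nM = 2000.0

[map.MAP7_C]
k_on = 0.0
k_off = 1.0
has_mtbd = false
has_projection = true
tail_weight = 0.0

[map.tau_chimera]
# tau microtubule-binding region grafted onto the MAP7 projection; affinity
# assumed comparable to FL MAP7 (not separately measured here)
k_on = 0.006666666666666667   # K_D = 150 nM, documented assumption
k_off = 1.0
has_mtbd = true
has_projection = true
tail_weight = 0.0

[motor.K560]
# constitutively active kinesin-1 dimer at saturating ATP
polarity = 1
step_size_sites = 2           # 16-nm labelled-head step
k_step = 50.0
p_forward0 = 0.860
p_side0 = 0.096
p_back0 = 0.044
k_detach0 = 0.8
p_detach_block = 0.50
binds_map7 = true
k_land_basal = 1.0
recruitment_gain = 5.0
n_clear = 0
activity0 = 1.0
map7_activation = false

[motor.K560_limiting_ATP]
# stepping-trace conditions: ~1 s dwells so individual 16-nm steps resolve
polarity = 1
step_size_sites = 2
k_step = 1.0
p_forward0 = 0.860
p_side0 = 0.096
p_back0 = 0.044
k_detach0 = 0.016             # detachment scales with catalytic cycling
p_detach_block = 0.50
binds_map7 = true
k_land_basal = 1.0
recruitment_gain = 5.0
n_clear = 0
activity0 = 1.0
map7_activation = false

[motor.K490]
# stalk truncation that removes the MAP7-binding site: no recruitment, no tether
polarity = 1
step_size_sites = 2
k_step = 50.0
p_forward0 = 0.860
p_side0 = 0.096
p_back0 = 0.044
k_detach0 = 0.8
p_detach_block = 0.50
binds_map7 = false
k_land_basal = 1.0
recruitment_gain = 0.0
n_clear = 0
activity0 = 1.0
map7_activation = false

[motor.FL_kinesin]
# full-length kinesin: autoinhibited at zero MAP7, relieved with decoration
polarity = 1
step_size_sites = 2
k_step = 50.0
p_forward0 = 0.860
p_side0 = 0.096
p_back0 = 0.044
k_detach0 = 0.8
p_detach_block = 0.50
binds_map7 = true
k_land_basal = 1.0
recruitment_gain = 5.0
n_clear = 0
activity0 = 0.005
map7_activation = true

[motor.DDR]
# dynein-dynactin-BicDR1: minus-end, obstacle-sensitive, no MAP7 linkage
polarity = -1
step_size_sites = 1
k_step = 50.0
p_forward0 = 0.88
p_side0 = 0.09
p_back0 = 0.03
k_detach0 = 0.8
p_detach_block = 1.0
binds_map7 = false
k_land_basal = 1.0
recruitment_gain = 0.0
n_clear = 8                   # consecutive free sites (incl. landing) per scored run
activity0 = 1.0
map7_activation = false

[tether]
reach_nm = 50.0               # spans the observed 16-64 nm displacement band
k_rebind = 10.0
sd_nm = 12.0                  # entropic-spring width of the rebinding kernel
k_release = 2.0

[noise]
localization_sd = 2.0
frame_interval = 0.1
intensity_cv = 0.1

[conditions]
high_decoration_nM = 1000.0   # theta = c/(c+111) ~ 0.90, near-saturating
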