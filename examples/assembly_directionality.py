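"""MAP7 switches the direction of a kinesin-dynein assembly.

An assembly couples autoinhibited full-length kinesin to dynein (DDR);
its travel direction is drawn from the two motors' run frequencies.  The
kinesin arm is calibrated once so 80% of assemblies are minus-end-directed
on an undecorated lattice; adding just 10 nM MAP7 relieves kinesin
autoinhibition while partially inhibiting dynein, flipping the majority to
the plus end (93% published).
"""

import tetherwalk as tw

fl_k = tw.motor_preset("FL_kinesin")
ddr = tw.motor_preset("DDR")
mp = tw.map_preset("FL_MAP7")

scale = tw.calibrate_assembly_scale(fl_k, ddr, mp, n_trials=400, seed=1, t_max=5.0)
print(f"kinesin-arm calibration scale at 0 nM: {scale:.3f}")

for conc in [0.0, 10.0]:
    out = tw.assembly_direction(fl_k, ddr, mp, conc, n_assemblies=400, seed=int(conc) + 2,
                                kinesin_scale=scale, n_trials=400, t_max=5.0)
    print(f"{conc:4.0f} nM MAP7: {100 * out['fraction_plus']:.0f}% plus-end, "
          f"{100 * out['fraction_minus']:.0f}% minus-end "
          f"(P_plus = {out['p_plus']:.2f}, n = {int(out['n_assemblies'])})")
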