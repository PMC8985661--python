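"""Construct-dependent microtubule binding under three lattice conditions.

Reproduces the logic of a fluorescence binding assay: each MAP construct
is scored at 1 uM on a bare lattice, on a lattice pre-saturated with a
rigor kinesin mutant (which blocks every MTBD site), and on a
subtilisin-treated lattice (tubulin tails removed, abolishing the weak
tail-mediated association).  Signals are normalized to full-length MAP7
on the bare lattice.
"""

import tetherwalk as tw

conditions = ["bare", "kinesin_predecorated", "subtilisin"]
print(f"{'construct':12s}" + "".join(f"{c:>24s}" for c in conditions))
for name in ["FL_MAP7", "MTBD_only", "dMTBD", "MAP7_N"]:
    params = tw.map_preset(name)
    vals = [tw.binding_assay(params, c, concentration=1000.0, seed=0)
            for c in conditions]
    print(f"{name:12s}" + "".join(f"{v:24.2f}" for v in vals))

print("\nMTBD binding is blocked by kinesin pre-decoration (competition for the"
      "\nsame dimer site); the MTBD-less construct binds only via tubulin tails"
      "\nand loses all binding when the tails are cleaved.")
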