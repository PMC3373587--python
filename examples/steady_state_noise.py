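"""Steady-state noise analysis of a Michaelis-Menten enzyme.

Builds the substrate-input enzyme model (malate dehydrogenase rate
constants, 4 uM total enzyme) in a 0.5 fl compartment, solves the
macroscopic rate equations by Newton iteration, the fluctuation covariance
by the steady-state Lyapunov equation, and the mesoscopic mean correction.
"""

import ssekit as sk

net = sk.make_michaelis_menten(volume_liters=5e-16)
print(net)
res = sk.emre_steady(sk.compile_system(net))

print(f"\n{'species':>8} {'RE [uM]':>10} {'EMRE [uM]':>10} {'sd [uM]':>10} {'CV':>8}")
for i, sid in enumerate(net.species_ids):
    print(
        f"{sid:>8} {res.phi_ss[i]/1e-6:>10.4f} {res.emre_ss[i]/1e-6:>10.4f} "
        f"{res.sd[i]/1e-6:>10.4f} {res.cv[i]:>8.4f}"
    )

print(
    "\nThe substrate has the largest relative noise (CV ~ 0.12) because the"
    "\nenzyme runs near saturation; the product is close to Poissonian"
    "\n(CV ~ 1/sqrt(copy number)).  At this volume the corrected (EMRE) means"
    "\nbarely differ from the rate equations, so the LNA noise levels are"
    "\ntrustworthy."
)
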