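"""Transient correlations of a cooperative enzyme.

A four-subunit positively cooperative enzyme (stepwise Michaelis constants
20, 2, 0.2, 0.02 uM) with substrate input, in a 1 fl compartment.  The
linear noise approximation gives the time-dependent correlation between the
fluctuations of any two species; substrate and free enzyme become
anti-correlated as the steady state is approached, through a damped
oscillation that signals noise-induced oscillations in single cells.
"""

import ssekit as sk

net = sk.make_cooperative_enzyme(volume_liters=1e-15)
tc = sk.lna_timecourse(
    sk.compile_system(net), sk.SolverConfig(t_final=10.0, n_points=101)
)
iS, iE = net.species_index("S"), net.species_index("E")

print("  t [s]   corr(S, E)")
for k in range(0, 101, 10):
    print(f"{tc.t[k]:7.1f}   {tc.corr[k, iS, iE]:+.4f}")

cv, _ = sk.noise_summaries(tc)
print(f"\nfinal substrate CV: {cv[-1, iS]:.3f}")
print(
    "The correlation relaxes to a negative value (binding partners are"
    "\nanti-correlated) and changes sign on the way: a damped oscillation"
    "\ntraceable to complex eigenvalues of the Jacobian."
)

import os, tempfile

path = os.path.join(tempfile.gettempdir(), "cooperative_timecourse.tsv")
sk.write_table(tc, path)
print(f"full table written to {path}")
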