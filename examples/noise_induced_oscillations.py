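"""Noise-induced oscillations in a single-gene circadian clock.

The strong-feedback clock circuit (one gene copy, cooperative promoter
repression by the nuclear protein, enzymatic mRNA/protein degradation,
0.2 fl) has an overdamped-looking macroscopic trajectory, but the
noise-corrected means keep ringing with a period of about a day, and a
single stochastic cell shows sustained oscillations at an even longer
period: rhythms that exist only because of molecular noise.
"""

from ssekit import studies

emre = studies.clock_emre_period(t_final=5.0)
print(f"EMRE mRNA peak-to-peak period: {emre['period_days']:.2f} days")
print(f"late ringing amplitude, EMRE vs RE: "
      f"{emre['ringing_emre']/emre['ringing_re']:.1f}x")

ssa = studies.clock_ssa_period(seed=1, t_final=55.0)
print(f"single-cell SSA dominant period (cytosolic protein): "
      f"{ssa['period_days']:.2f} days")
print(
    "\nThe corrected means oscillate where the rate equations flatten out"
    "\n(population-level synchrony induced by noise), and the single-cell"
    "\nrhythm runs slower than the ensemble ringing: the stochastic"
    "\nfrequency is shifted below the linearized one."
)
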