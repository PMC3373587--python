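"""Physical constants and shared symbols."""

import sympy as sp

#: Avogadro constant in 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Symbolic effective system size: the number of molecules per unit
#: concentration (Omega * N_A when concentrations are molar, Omega when the
#: substance unit is "item").  Propensities and SSE tensors carry this symbol
#: so that the volume expansion can be performed exactly.
SYSTEM_SIZE = sp.Symbol("Omega", positive=True)
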