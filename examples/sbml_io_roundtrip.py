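"""Writing and reading models as SBML (Level 2 Version 4).

Any network can be exported as SBML and read back without loss; files with
constructs outside the stochastic subset (events, rules, reversible
reactions, constant species) are rejected with named validation errors.
"""

import tempfile, os

import ssekit as sk

net = sk.make_paper_model("F1")
with tempfile.TemporaryDirectory() as d:
    path = os.path.join(d, "enzyme.xml")
    sk.emit_sbml(net, path)
    print(f"wrote {os.path.getsize(path)} bytes of SBML")

    report = sk.validate_network(path)
    print(f"validation: ok={report.ok}, {len(report.errors)} errors")

    net2 = sk.parse_sbml(path)
    print(f"re-parsed: {net2}")
    res = sk.emre_steady(sk.compile_system(net2))
    print(f"substrate CV from the round-tripped model: "
          f"{res.cv[net2.species_index('S')]:.4f}")
    print("identical to the directly built model: the kinetic laws are"
          "\nstored as exact mesoscopic propensities.")
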