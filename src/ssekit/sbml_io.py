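"""SBML (Level 2 Version 4 subset) import, validation and export.

The supported subset covers single-compartment models with unit definitions,
species, global/local parameters and irreversible reactions with kinetic
laws.  The kinetic law is taken as the mesoscopic propensity source: species
symbols denote molar concentrations, the compartment symbol the volume in
litres, and the math must evaluate to events per model time unit.  On import
species symbols are substituted by count variables (``X -> n_X / Omega_eff``)
so the stored propensity is the count-space rate.

Constructs outside the stochastic subset (events, rules, reversible
reactions, constant/boundary species, explicit time dependence) are reported
through :func:`validate_network` rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp

import libsbml

from .constants import AVOGADRO, SYSTEM_SIZE
from .network import ReactionNetwork, ReactionDef, SpeciesDef, ValueKind, count_symbol

__all__ = [
    "ParseError",
    "ValidationError",
    "ValidationReport",
    "parse_sbml",
    "validate_network",
    "emit_sbml",
    "load_document",
]

_SECONDS_PER = {"second": 1.0, "minute": 60.0, "hour": 3600.0, "day": 86400.0}


class ParseError(RuntimeError):
    pass


class ValidationError(RuntimeError):
    def __init__(self, report):
        self.report = report
        msg = "; ".join(f"{c}: {m}" for c, m in report.errors)
        super().__init__(f"model failed stochastic validation ({msg})")


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)  # (code, message)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def load_document(path: str) -> "libsbml.SBMLDocument":
    doc = libsbml.readSBMLFromFile(str(path))
    n_err = doc.getNumErrors()
    fatal = [
        doc.getError(i)
        for i in range(n_err)
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if fatal:
        e = fatal[0]
        raise ParseError(
            f"cannot read SBML file {path!r}: line {e.getLine()}: {e.getMessage()}"
        )
    if doc.getModel() is None:
        raise ParseError(f"no model element in SBML file {path!r}")
    return doc


def validate_network(doc_or_path) -> ValidationReport:
    """Check an SBML document against the supported stochastic subset."""
    doc = doc_or_path if isinstance(doc_or_path, libsbml.SBMLDocument) \
        else load_document(doc_or_path)
    model = doc.getModel()
    rep = ValidationReport()
    if model.getNumEvents() > 0:
        rep.errors.append(
            ("UNSUPPORTED_EVENT", "events are not supported for stochastic models")
        )
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        rep.errors.append(
            (
                "UNSUPPORTED_RULE",
                f"rule for {rule.getVariable() or 'algebraic constraint'}: "
                "parameters and species must not be defined by rules",
            )
        )
    if model.getNumCompartments() != 1:
        rep.errors.append(
            (
                "MULTI_COMPARTMENT",
                f"{model.getNumCompartments()} compartments; only "
                "single-compartment models are supported",
            )
        )
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        if rxn.getReversible():
            rep.errors.append(
                (
                    "REVERSIBLE_REACTION",
                    f"reaction {rxn.getId()!r}: the reversible attribute cannot "
                    "be validated for stochastic models; split into "
                    "irreversible steps",
                )
            )
        kl = rxn.getKineticLaw()
        if kl is None:
            rep.errors.append(
                ("MISSING_KINETIC_LAW", f"reaction {rxn.getId()!r} has no kinetic law")
            )
        elif kl.getMath() is not None and _references_time(kl.getMath()):
            rep.errors.append(
                (
                    "TIME_DEPENDENT_RATE",
                    f"reaction {rxn.getId()!r}: explicit time dependence in the "
                    "kinetic law is not supported",
                )
            )
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        if s.getConstant() or s.getBoundaryCondition():
            rep.errors.append(
                (
                    "CONSTANT_SPECIES",
                    f"species {s.getId()!r} is constant or a boundary condition; "
                    "all species must evolve freely",
                )
            )
    return rep


def _references_time(ast) -> bool:
    if ast.getType() == libsbml.AST_NAME_TIME:
        return True
    return any(_references_time(ast.getChild(i)) for i in range(ast.getNumChildren()))


def _time_unit(model) -> str:
    ud = model.getUnitDefinition("time")
    if ud is not None and ud.getNumUnits() == 1:
        u = ud.getUnit(0)
        if u.getKind() == libsbml.UNIT_KIND_SECOND:
            sec = u.getMultiplier() * 10 ** u.getScale()
            for name, s in _SECONDS_PER.items():
                if abs(sec - s) < 1e-6 * s:
                    return name
    return "second"


def parse_sbml(path: str, strict: bool = True) -> ReactionNetwork:
    """Read an SBML file into a :class:`ReactionNetwork`.

    With ``strict`` (default) the document must pass
    :func:`validate_network`; violations raise :class:`ValidationError` and
    no partial network is returned.
    """
    doc = load_document(path)
    if strict:
        rep = validate_network(doc)
        if not rep.ok:
            raise ValidationError(rep)
    model = doc.getModel()
    if model.getNumCompartments() != 1:
        raise ParseError("only single-compartment models are supported")
    comp = model.getCompartment(0)
    volume = comp.getSize() if comp.isSetSize() else 1.0

    species = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        if s.isSetInitialConcentration():
            init, kind = s.getInitialConcentration(), ValueKind.CONCENTRATION
        elif s.isSetInitialAmount():
            # amounts are stored in moles; convert to molecule counts
            init, kind = s.getInitialAmount() * AVOGADRO, ValueKind.AMOUNT
        else:
            init, kind = 0.0, ValueKind.CONCENTRATION
        species.append(
            SpeciesDef(
                id=s.getId(),
                name=s.getName() or s.getId(),
                compartment_id=s.getCompartment(),
                initial_value=init,
                value_kind=kind,
            )
        )

    params = {}
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        params[p.getId()] = p.getValue()

    # symbol table for kinetic-law math: species ids become count variables
    local = {s.id: count_symbol(s.id) / SYSTEM_SIZE for s in species}
    local[comp.getId()] = SYSTEM_SIZE / AVOGADRO
    local["N_A"] = sp.Float(AVOGADRO)
    for name, val in params.items():
        if name != "N_A":
            local[name] = sp.Float(val)

    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        react = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            st = ref.getStoichiometry()
            if st != int(st):
                raise ParseError(
                    f"reaction {rxn.getId()!r}: non-integer stoichiometry"
                )
            react[ref.getSpecies()] = react.get(ref.getSpecies(), 0) + int(st)
        prod = {}
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            st = ref.getStoichiometry()
            if st != int(st):
                raise ParseError(
                    f"reaction {rxn.getId()!r}: non-integer stoichiometry"
                )
            prod[ref.getSpecies()] = prod.get(ref.getSpecies(), 0) + int(st)
        kl = rxn.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise ParseError(f"reaction {rxn.getId()!r} has no kinetic law")
        formula = libsbml.formulaToL3String(kl.getMath())
        scope = dict(local)
        for k in range(kl.getNumParameters()):  # local parameters are inlined
            p = kl.getParameter(k)
            scope[p.getId()] = sp.Float(p.getValue())
        try:
            expr = sp.parse_expr(formula.replace("^", "**"), local_dict=scope)
        except Exception as exc:
            raise ParseError(
                f"reaction {rxn.getId()!r}: cannot parse kinetic law "
                f"{formula!r}: {exc}"
            ) from exc
        expr = sp.cancel(sp.together(expr))
        order = sum(react.values())
        reactions.append(
            ReactionDef(
                id=rxn.getId() or f"reaction_{i}",
                reactant_stoich=react,
                product_stoich=prod,
                propensity=expr,
                is_elementary=order <= 2 and expr.is_polynomial(),
            )
        )

    return ReactionNetwork(
        species=species,
        reactions=reactions,
        volume_liters=volume,
        parameters=params,
        time_unit=_time_unit(model),
        name=model.getId() or "sbml_model",
    )


def emit_sbml(net: ReactionNetwork, path: str) -> None:
    """Write a network as SBML L2v4 readable back by :func:`parse_sbml`."""
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(net.name.replace("-", "_") or "model")

    if net.time_unit in _SECONDS_PER and net.time_unit != "second":
        ud = model.createUnitDefinition()
        ud.setId("time")
        u = ud.createUnit()
        u.setKind(libsbml.UNIT_KIND_SECOND)
        u.setMultiplier(_SECONDS_PER[net.time_unit])
        u.setExponent(1)
        u.setScale(0)

    comp = model.createCompartment()
    comp.setId("cell")
    comp.setSize(net.volume_liters)
    comp.setUnits("litre")

    for s in net.species:
        sb = model.createSpecies()
        sb.setId(s.id)
        sb.setName(s.name)
        sb.setCompartment("cell")
        sb.setConstant(False)
        sb.setBoundaryCondition(False)
        if s.value_kind is ValueKind.CONCENTRATION:
            sb.setInitialConcentration(s.initial_value)
        else:
            sb.setInitialAmount(s.initial_value / AVOGADRO)  # moles

    pna = model.createParameter()
    pna.setId("N_A")
    pna.setValue(AVOGADRO)
    pna.setConstant(True)
    for name, val in net.parameters.items():
        if name == "N_A":
            continue
        p = model.createParameter()
        p.setId(name)
        p.setValue(float(val))
        p.setConstant(True)

    # count variable -> concentration * volume * N_A
    sub = {count_symbol(s.id): sp.Symbol(s.id) * sp.Symbol("cell") * sp.Symbol("N_A")
           for s in net.species}
    sub[SYSTEM_SIZE] = sp.Symbol("cell") * sp.Symbol("N_A")

    for rxn in net.reactions:
        rb = model.createReaction()
        rb.setId(rxn.id)
        rb.setReversible(False)
        rb.setFast(False)
        for sid, st in rxn.reactant_stoich.items():
            ref = rb.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(st))
        for sid, st in rxn.product_stoich.items():
            ref = rb.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(st))
        kl = rb.createKineticLaw()
        expr = sp.cancel(sp.together(rxn.propensity.subs(sub)))
        ast = libsbml.parseL3Formula(sp.sstr(expr).replace("**", "^"))
        if ast is None:
            raise ValueError(
                f"reaction {rxn.id!r}: cannot encode propensity {expr} as MathML"
            )
        kl.setMath(ast)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path!r}")
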