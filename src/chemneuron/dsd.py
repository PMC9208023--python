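"""Two-domain DNA strand-displacement (DSD) realization of the neuron (d-CN).

Every signal species is a two-domain strand (toehold + long recognition
domain); the learning signal is the three-domain strand ``<b te_m^ b>``.
Each catalytic reaction of the abstract network is realized by a Join-Fork
gate pair: the Join gate binds the two reactants in sequence (releasing a
waste strand, then a translator strand), the translator triggers the Fork
gate, which releases the products with the help of a fuel strand; seal
strands close both gates to prevent rebinding.  The sigmoidal activation
function is a single extended polymer complex that consumes ``m`` state
strands ``B`` before releasing the learning signal.

Concentrations are in uM and time in seconds throughout this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .inputs import BolusEvent, InputSchedule
from .models import Reaction, ReactionNetwork, Species

__all__ = [
    "Domain", "Strand", "GateComplex", "DSDCircuit",
    "build_dcn", "count_domains", "compile_to_crn",
    "export_dsd_script", "parse_dsd_script", "audit_stoichiometry",
    "default_rates", "collector_schedule",
]


# ---------------------------------------------------------------------------
# structural types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Domain:
    name: str
    kind: str            # "toehold" | "long"
    family: str          # "channel" | "core" | "activation"

    def render(self) -> str:
        return self.name + "^" if self.kind == "toehold" else self.name


@dataclass(frozen=True)
class Strand:
    """An upper single strand: an ordered list of domain tokens.

    Tokens are rendered names (toeholds carry the ``^`` marker); a trailing
    ``*`` marks a complemented domain.
    """

    name: str
    domains: tuple[str, ...]
    role: str = "helper"
    concentration: float = 0.0

    def render(self) -> str:
        return "<" + " ".join(self.domains) + ">"


@dataclass(frozen=True)
class GateComplex:
    """A double-stranded gate in the bracket dialect.

    ``segments`` is an ordered tuple of ``(kind, tokens)`` groups with kind
    one of ``"lower"`` (``{...}``, exposed lower-strand overhang),
    ``"duplex"`` (``[...]``, double-stranded segment) or ``"upper"``
    (``<...>``, upper-strand overhang).  Rendering joins consecutive duplex
    groups with ``": "``, puts a space after a lower group, and glues an
    upper overhang to the preceding duplex — reproducing forms such as
    ``{tb^*} [b te0^]: [b te1^]<b>``.
    """

    name: str
    segments: tuple[tuple[str, tuple[str, ...]], ...]
    role: str = "gate"    # "Join" | "Fork" | "activation polymer" | "garbage collector"
    concentration: float = 0.0

    def render(self) -> str:
        parts: list[str] = []
        prev = None
        for kind, tokens in self.segments:
            body = " ".join(tokens)
            if kind == "lower":
                txt = "{" + body + "}"
            elif kind == "duplex":
                txt = "[" + body + "]"
            elif kind == "upper":
                txt = "<" + body + ">"
            else:
                raise ValueError(f"unknown segment kind {kind!r}")
            if prev is None:
                parts.append(txt)
            elif prev == "lower":
                parts.append(" " + txt)
            elif prev == "duplex" and kind == "duplex":
                parts.append(": " + txt)
            elif prev == "duplex" and kind == "upper":
                parts.append(txt)
            elif prev == "duplex" and kind == "lower":
                parts.append(" " + txt)
            else:  # upper followed by anything
                parts.append(" " + txt)
            prev = kind
        return "".join(parts)


_STRUCT_RE = re.compile(r"\{([^}]*)\}|\[([^\]]*)\]|<([^>]*)>")


def parse_structure(text: str) -> tuple[tuple[str, tuple[str, ...]], ...]:
    """Parse a bracket-dialect structure back into segment groups."""
    segments = []
    pos = 0
    for mobj in _STRUCT_RE.finditer(text):
        gap = text[pos:mobj.start()]
        if gap.strip() not in ("", ":"):
            raise ValueError(f"unparseable separator {gap!r} in {text!r}")
        pos = mobj.end()
        lower, duplex, upper = mobj.groups()
        if lower is not None:
            segments.append(("lower", tuple(lower.split())))
        elif duplex is not None:
            segments.append(("duplex", tuple(duplex.split())))
        else:
            segments.append(("upper", tuple(upper.split())))
    if text[pos:].strip():
        raise ValueError(f"trailing text {text[pos:]!r} in structure")
    return tuple(segments)


@dataclass
class DSDCircuit:
    """Domains, strands and gate complexes of a compiled d-CN."""

    N: int
    m: int
    domains: list[Domain] = field(default_factory=list)
    strands: list[Strand] = field(default_factory=list)
    gates: list[GateComplex] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def domain(self, name: str) -> Domain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def strand(self, name: str) -> Strand:
        for s in self.strands:
            if s.name == name:
                return s
        raise KeyError(name)

    def gate(self, name: str) -> GateComplex:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(name)

    def used_domain_names(self) -> set[str]:
        used: set[str] = set()
        for s in self.strands:
            for tok in s.domains:
                used.add(tok.rstrip("*^").rstrip("^"))
        for g in self.gates:
            for _, tokens in g.segments:
                for tok in tokens:
                    used.add(tok.rstrip("*").rstrip("^"))
        return used

    def validate(self) -> None:
        declared = {d.name for d in self.domains}
        missing = self.used_domain_names() - declared
        if missing:
            raise ValueError(f"undeclared domains referenced: {sorted(missing)}")
        names = [s.name for s in self.strands] + [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strand/gate names")


# ---------------------------------------------------------------------------
# circuit construction
# ---------------------------------------------------------------------------

#: default initial concentrations (uM)
DEFAULT_CONCENTRATIONS = {
    "signal_modulation_fuel": 25000.0,
    "signal_integration_fuel": 50000.0,
    "weight_accumulation_fuel": 10000.0,
    "fsi": 50000.0,
    "bolus": 10.0,
    "polymer": 50.0,
    "collector_B": 12.0,
    "collector_H": 0.1,
    "collector_period": 1000.0,
}


def _polymer_segments(m: int) -> tuple[tuple[str, tuple[str, ...]], ...]:
    """Activation polymer: ``{tb^*} [b te0^]: ([b tb^]: [b tek^]:)* [b tem^]<b>``."""
    segs: list[tuple[str, tuple[str, ...]]] = [
        ("lower", ("tb^*",)), ("duplex", ("b", "te0^"))]
    for k in range(1, m):
        segs.append(("duplex", ("b", "tb^")))
        segs.append(("duplex", ("b", f"te{k}^")))
    segs.append(("duplex", ("b", f"te{m}^")))
    segs.append(("upper", ("b",)))
    return tuple(segs)


def build_dcn(N: int, m: int, concentrations: dict | None = None) -> DSDCircuit:
    """Generate the two-domain d-CN circuit for ``N`` channels, chain length ``m``.

    Per channel the circuit carries three Join-Fork gate pairs (signal
    integration ``Fsi_n + A_n -> A_n + B``, signal modulation
    ``A_n + H_n -> H_n + B`` and weight accumulation ``A_n + E -> E + H_n``),
    one activation polymer of length ``m`` shared by all channels, and
    garbage collectors for ``B`` and each ``H_n``.
    """
    if N < 1 or m < 1:
        raise ValueError("N and m must be >= 1")
    conc = dict(DEFAULT_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)

    c = DSDCircuit(N=N, m=m, metadata={"concentrations": conc})
    # --- domains -----------------------------------------------------------
    for t in ("ta", "th", "tb", "tfsi", "tism", "tisi"):
        c.domains.append(Domain(t, "toehold", "core"))
    for n in range(1, N + 1):
        c.domains.append(Domain(f"tiwa{n}", "toehold", "core"))
    for k in range(m + 1):
        c.domains.append(Domain(f"te{k}", "toehold", "activation"))
    for d in ("b", "i"):
        c.domains.append(Domain(d, "long", "core"))
    for n in range(1, N + 1):
        for d in (f"a{n}", f"h{n}", f"fsi{n}"):
            c.domains.append(Domain(d, "long", "channel"))

    # --- signal strands ----------------------------------------------------
    c.strands.append(Strand("B", ("tb^", "b"), "state B", 0.0))
    c.strands.append(Strand("E", ("b", f"te{m}^", "b"), "learning signal", 0.0))
    for n in range(1, N + 1):
        c.strands.append(Strand(f"A{n}", ("ta^", f"a{n}"), f"input A_{n}", 0.0))
        c.strands.append(Strand(f"H{n}", ("th^", f"h{n}"), f"weight H_{n}", 0.0))
        c.strands.append(Strand(f"Fsi{n}", ("tfsi^", f"fsi{n}"),
                                "fuel", conc["fsi"]))

    # --- Join-Fork gate pairs ---------------------------------------------
    def aux_strand(name: str, domains: tuple[str, ...], role: str,
                   conc: float) -> None:
        """Add a helper/seal strand, merging identical strands: cascades that
        release the same product share one physical helper/seal species."""
        for idx, s in enumerate(c.strands):
            if s.domains == domains:
                c.strands[idx] = Strand(s.name, s.domains, s.role,
                                        s.concentration + conc)
                return
        c.strands.append(Strand(name, domains, role, conc))

    def join_fork(tag: str, n: int, t1: str, r1: str, t2: str, r2: str,
                  tj: str, tp1: str, p1: str, tp2: str, p2: str,
                  fuel: float, three_domain: bool = False) -> None:
        """Add one Join-Fork pair with its translator, helper and seals.

        Reactants ``<t1^ r1>`` + ``<t2^ r2>`` -> products ``<tp1^ p1>`` +
        ``<tp2^ p2>`` via translator ``<r2 tj^>``.  ``three_domain`` marks
        the weight-accumulation variant whose first reactant and first
        product are the three-domain learning signal (branched Fork).
        """
        join = GateComplex(
            f"Join_{tag}{n}",
            (("lower", (f"{t1}^*",)),
             ("duplex", (r1, f"{t2}^")),
             ("duplex", (r2, f"{tj}^")),
             ("duplex", ("i",))),
            "Join", fuel)
        fork_segs: list[tuple[str, tuple[str, ...]]] = [
            ("duplex", ("i", f"{tp2}^")),
            ("duplex", (p2, f"{tp1}^")),
            ("duplex", (p1,))]
        if three_domain:
            # branched Fork: a long domain b branches off the duplex so the
            # released first product is the three-domain learning signal
            fork_segs.append(("upper", ("b",)))
        fork_segs.append(("lower", (f"{tj}^*",)))
        fork = GateComplex(f"Fork_{tag}{n}", tuple(fork_segs), "Fork", fuel)
        c.gates.extend([join, fork])
        aux_strand(f"Helper_{p2}_{tp1}", (p2, f"{tp1}^"), "helper", fuel)
        aux_strand(f"Seal_{tj}_i", (f"{tj}^", "i"), "seal", fuel)
        aux_strand(f"Seal_i_{tp2}", ("i", f"{tp2}^"), "seal", fuel)

    for n in range(1, N + 1):
        # signal integration: Fsi_n + A_n -> A_n + B
        join_fork("SI", n, "tfsi", f"fsi{n}", "ta", f"a{n}", "tisi",
                  "ta", f"a{n}", "tb", "b",
                  conc["signal_integration_fuel"])
        # signal modulation: A_n + H_n -> H_n + B (weight-catalyzed input)
        join_fork("SM", n, "th", f"h{n}", "ta", f"a{n}", "tism",
                  "th", f"h{n}", "tb", "b",
                  conc["signal_modulation_fuel"])
        # weight accumulation: A_n + E -> E + H_n (three-domain reactant)
        join_fork("WA", n, f"te{m}", "b", "ta", f"a{n}", f"tiwa{n}",
                  f"te{m}", "b", "th", f"h{n}",
                  conc["weight_accumulation_fuel"], three_domain=True)

    # --- activation polymer and its stepping fuels -------------------------
    c.gates.append(GateComplex("Polymer", _polymer_segments(m),
                               "activation polymer", conc["polymer"]))
    for k in range(m):
        c.strands.append(Strand(f"Eh{k}", ("b", f"te{k}^"), "fuel",
                                conc["polymer"] * 20.0))

    # --- garbage collectors -------------------------------------------------
    c.gates.append(GateComplex("CollectB", (("lower", ("tb^*",)),
                                            ("duplex", ("b",))),
                               "garbage collector", conc["collector_B"]))
    for n in range(1, N + 1):
        c.gates.append(GateComplex(f"CollectH{n}", (("lower", ("th^*",)),
                                                    ("duplex", (f"h{n}",))),
                                   "garbage collector", conc["collector_H"]))
    c.validate()
    return c


def count_domains(circuit: DSDCircuit) -> dict:
    """Count distinct domain definitions by class.

    ``core_toeholds`` excludes the activation polymer's te-family; the
    printed closed forms are ``6 + N`` core toeholds, ``m + 1`` activation
    toeholds and ``2 + 3 N`` long domains.
    """
    used = circuit.used_domain_names()
    te = re.compile(r"^te\d+$")
    toeholds = {d.name for d in circuit.domains
                if d.kind == "toehold" and d.name in used}
    longs = {d.name for d in circuit.domains
             if d.kind == "long" and d.name in used}
    return {
        "core_toeholds": len({t for t in toeholds if not te.match(t)}),
        "activation_toeholds": len({t for t in toeholds if te.match(t)}),
        "long_domains": len(longs),
    }


# ---------------------------------------------------------------------------
# compilation to a reaction network
# ---------------------------------------------------------------------------

def default_rates() -> dict:
    """Per-toehold binding (uM^-1 s^-1) and unbinding (s^-1) rate constants.

    Within experimentally measured strand-displacement ranges; the ta and th
    toeholds bind more slowly than the rest so that input and weight strands
    interact on the slow, signal timescale.
    """
    fast = {"bind": 1e-4, "unbind": 1.0}
    slow = {"bind": 2e-7, "unbind": 1.0}
    rates = {t: dict(fast) for t in ("tb", "tfsi", "tism", "tisi")}
    rates["ta"] = dict(slow)
    rates["th"] = dict(slow)
    return rates


def _rate(rates: dict, toehold: str, which: str, default_key: str = "_default"):
    if toehold in rates:
        return rates[toehold][which]
    if default_key in rates:
        return rates[default_key][which]
    raise KeyError(f"no rate supplied for toehold {toehold!r}")


#: roles whose species count as signals in the stoichiometry audit
_SIGNAL_ROLES = ("input", "weight", "state", "learning signal")


def compile_to_crn(circuit: DSDCircuit, rates: dict | None = None) -> ReactionNetwork:
    """Expand every Join-Fork cascade and the activation polymer into
    elementary bimolecular steps.

    Each cascade follows the six-step sequence: reactant-1 binding (waste
    released, reversible), reactant-2 binding (translator released,
    reversible), Join sealing, Fork triggering (first product released),
    helper-mediated second-product release, Fork sealing.  Net stoichiometry
    over signal species equals the abstract reaction (see
    :func:`audit_stoichiometry`).
    """
    if rates is None:
        rates = default_rates()
        rates["_default"] = {"bind": 1e-4, "unbind": 1.0}
        for n in range(1, circuit.N + 1):
            rates.setdefault(f"tiwa{n}", {"bind": 1e-4, "unbind": 1.0})
        for k in range(circuit.m + 2):
            rates.setdefault(f"te{k}", {"bind": 1e-4, "unbind": 1.0})
    net = ReactionNetwork(metadata={
        "model": "dcn", "N": circuit.N, "m": circuit.m,
        "signal_species": [], "fuel_species": [], "waste_species": [],
        "cascades": {},
    })
    added: set[str] = set()

    def sp(name: str, conc: float = 0.0, klass: str = "fuel") -> str:
        if name not in added:
            net.species.append(Species(name, "bulk", conc))
            added.add(name)
            net.metadata[f"{klass}_species"].append(name)
        return name

    # signal strands
    sp("B", 0.0, "signal")
    sp("E", 0.0, "signal")
    for n in range(1, circuit.N + 1):
        sp(f"A{n}", 0.0, "signal")
        sp(f"H{n}", 0.0, "signal")
        sp(f"Fsi{n}", circuit.strand(f"Fsi{n}").concentration, "fuel")

    def cascade(tag: str, n: int, r1: str, r2: str, p1: str, p2: str,
                t1: str, t2: str, tj: str, tp1: str, tp2: str) -> list[str]:
        """Emit the six-step Join-Fork expansion; returns reaction labels."""
        jname, fname = f"Join_{tag}{n}", f"Fork_{tag}{n}"
        j0 = sp(f"{jname}_s0", circuit.gate(jname).concentration)
        j1, j2, j3 = sp(f"{jname}_s1"), sp(f"{jname}_s2"), sp(f"{jname}_s3")
        f0 = sp(f"{fname}_s0", circuit.gate(fname).concentration)
        f1, f2, f3 = sp(f"{fname}_s1"), sp(f"{fname}_s2"), sp(f"{fname}_s3")
        w1 = sp(f"W_{tag}{n}_r1", 0.0, "waste")
        trans = sp(f"T_{tag}{n}")
        wj = sp(f"W_{tag}{n}_join", 0.0, "waste")
        wf = sp(f"W_{tag}{n}_fork", 0.0, "waste")
        helper_name = f"Helper_{p2.lower()}_{tp1}"
        jseal_name = f"Seal_{tj}_i"
        fseal_name = f"Seal_i_{tp2}"
        helper = sp(helper_name, circuit.strand(helper_name).concentration)
        jseal = sp(jseal_name, circuit.strand(jseal_name).concentration)
        fseal = sp(fseal_name, circuit.strand(fseal_name).concentration)
        labels = []

        def add(reactants, products, k, label):
            net.reactions.append(Reaction(tuple(reactants), tuple(products),
                                          k, label))
            labels.append(label)

        add((r1, j0), (j1, w1), _rate(rates, t1, "bind"), f"{tag}{n}_join_bind1")
        add((j1, w1), (r1, j0), _rate(rates, t1, "unbind") * 1e-4,
            f"{tag}{n}_join_bind1_rev")
        add((r2, j1), (j2, trans), _rate(rates, t2, "bind"), f"{tag}{n}_join_bind2")
        add((j2, trans), (r2, j1), _rate(rates, t2, "unbind") * 1e-4,
            f"{tag}{n}_join_bind2_rev")
        add((jseal, j2), (j3, wj), _rate(rates, tj, "bind"), f"{tag}{n}_join_seal")
        add((trans, f0), (f1, p1), _rate(rates, tj, "bind"), f"{tag}{n}_fork_trigger")
        add((helper, f1), (f2, p2), _rate(rates, tp1, "bind"), f"{tag}{n}_fork_helper")
        add((fseal, f2), (f3, wf), _rate(rates, tp2, "bind"), f"{tag}{n}_fork_seal")
        return labels

    for n in range(1, circuit.N + 1):
        net.metadata["cascades"][f"SI{n}"] = {
            "abstract": {"reactants": [f"Fsi{n}", f"A{n}"],
                         "products": [f"A{n}", "B"]},
            "labels": cascade("SI", n, f"Fsi{n}", f"A{n}", f"A{n}", "B",
                              "tfsi", "ta", "tisi", "ta", "tb"),
        }
        net.metadata["cascades"][f"SM{n}"] = {
            "abstract": {"reactants": [f"H{n}", f"A{n}"],
                         "products": [f"H{n}", "B"]},
            "labels": cascade("SM", n, f"H{n}", f"A{n}", f"H{n}", "B",
                              "th", "ta", "tism", "th", "tb"),
        }
        net.metadata["cascades"][f"WA{n}"] = {
            "abstract": {"reactants": ["E", f"A{n}"],
                         "products": ["E", f"H{n}"]},
            "labels": cascade("WA", n, "E", f"A{n}", "E", f"H{n}",
                              f"te{circuit.m}", "ta", f"tiwa{n}",
                              f"te{circuit.m}", "th"),
        }

    # activation polymer: alternating B / stepping-fuel binding, reversible;
    # the final step releases the learning signal E
    m = circuit.m
    poly_conc = circuit.gate("Polymer").concentration
    states = [sp("Poly_s0", poly_conc)]
    for j in range(1, 2 * m + 1):
        states.append(sp(f"Poly_s{j}"))
    plabels = []
    for k in range(m):
        b_on = _rate(rates, "tb", "bind")
        b_off = _rate(rates, "tb", "unbind") * 1e-4
        net.reactions.append(Reaction((states[2 * k], "B"), (states[2 * k + 1],),
                                      b_on, f"poly_bindB_{k}"))
        net.reactions.append(Reaction((states[2 * k + 1],), (states[2 * k], "B"),
                                      b_off, f"poly_bindB_{k}_rev"))
        plabels += [f"poly_bindB_{k}", f"poly_bindB_{k}_rev"]
        eh = sp(f"Eh{k}", circuit.strand(f"Eh{k}").concentration)
        e_on = _rate(rates, f"te{k}", "bind")
        e_off = _rate(rates, f"te{k}", "unbind") * 1e-4
        if k < m - 1:
            net.reactions.append(Reaction((states[2 * k + 1], eh),
                                          (states[2 * k + 2],),
                                          e_on, f"poly_step_{k}"))
            net.reactions.append(Reaction((states[2 * k + 2],),
                                          (states[2 * k + 1], eh),
                                          e_off, f"poly_step_{k}_rev"))
        else:
            net.reactions.append(Reaction((states[2 * k + 1], eh),
                                          (states[2 * k + 2], "E"),
                                          e_on, f"poly_step_{k}"))
            net.reactions.append(Reaction((states[2 * k + 2], "E"),
                                          (states[2 * k + 1], eh),
                                          e_off, f"poly_step_{k}_rev"))
        plabels += [f"poly_step_{k}", f"poly_step_{k}_rev"]
    net.metadata["cascades"]["Polymer"] = {
        "abstract": {"reactants": ["B"] * m, "products": ["E"]},
        "labels": plabels,
    }

    # garbage collection (sequestration)
    gb = sp("CollectB", circuit.gate("CollectB").concentration)
    wb = sp("W_CollectB", 0.0, "waste")
    net.reactions.append(Reaction(("B", gb), (wb,),
                                  _rate(rates, "tb", "bind"), "collect_B"))
    for n in range(1, circuit.N + 1):
        gh = sp(f"CollectH{n}", circuit.gate(f"CollectH{n}").concentration)
        wh = sp(f"W_CollectH{n}", 0.0, "waste")
        net.reactions.append(Reaction((f"H{n}", gh), (wh,),
                                      _rate(rates, "th", "bind") * 500,
                                      f"collect_H{n}"))
    net.validate()
    return net


def audit_stoichiometry(net: ReactionNetwork) -> dict:
    """Check each compiled cascade's net stoichiometry over signal species
    against its abstract reaction; returns {cascade: bool}."""
    signal = set(net.metadata["signal_species"])
    by_label = {r.label: r for r in net.reactions}
    result = {}
    for name, info in net.metadata["cascades"].items():
        net_change: dict[str, int] = {}
        for label in info["labels"]:
            if label.endswith("_rev"):
                continue  # forward direction of each reversible step
            r = by_label[label]
            for s_ in r.reactants:
                net_change[s_] = net_change.get(s_, 0) - 1
            for s_ in r.products:
                net_change[s_] = net_change.get(s_, 0) + 1
        expected: dict[str, int] = {}
        for s_ in info["abstract"]["reactants"]:
            expected[s_] = expected.get(s_, 0) - 1
        for s_ in info["abstract"]["products"]:
            expected[s_] = expected.get(s_, 0) + 1
        got = {s_: v for s_, v in net_change.items() if s_ in signal and v != 0}
        want = {s_: v for s_, v in expected.items() if s_ in signal and v != 0}
        result[name] = got == want
    return result


def collector_schedule(circuit: DSDCircuit, horizon: float) -> list[BolusEvent]:
    """Periodic garbage-collector replenishment as ordinary bolus events."""
    conc = circuit.metadata["concentrations"]
    period = conc["collector_period"]
    out = []
    t = period
    while t <= horizon:
        out.append(BolusEvent(0, t, conc["collector_B"], 1.0, species="CollectB"))
        for n in range(1, circuit.N + 1):
            out.append(BolusEvent(0, t, conc["collector_H"], 1.0,
                                  species=f"CollectH{n}"))
        t += period
    return out


def dcn_input_schedule(circuit: DSDCircuit, task, include_collectors: bool = True
                       ) -> InputSchedule:
    """Realize an input task for the compiled d-CN.

    Boli inject ``bolus`` uM of the input strand ``A_n`` directly (strand
    injections are instantaneous; there is no precursor species in the DNA
    circuit), and the garbage collectors are replenished periodically.
    """
    from .inputs import generate_schedule

    conc = circuit.metadata["concentrations"]
    base = generate_schedule(task, 1, 1.0)
    events = [BolusEvent(e.channel, e.time, conc["bolus"], 1.0,
                         species=f"A{e.channel}") for e in base.events]
    if include_collectors:
        events += collector_schedule(circuit, task.horizon)
    return InputSchedule(events, task)


# ---------------------------------------------------------------------------
# script export / import
# ---------------------------------------------------------------------------

def export_dsd_script(circuit: DSDCircuit) -> str:
    """Emit a Visual-DSD-style script: domain declarations, strands with
    initial concentrations, and gate complexes in the bracket dialect."""
    lines = [f"(* d-CN circuit: N={circuit.N}, m={circuit.m} *)"]
    for d in circuit.domains:
        deg = "toehold" if d.kind == "toehold" else "long"
        lines.append(f"def {d.render()} = {deg} ({d.family})")
    for s in circuit.strands:
        lines.append(f"strand {s.name} = {s.render()} @ {s.concentration:g} (* {s.role} *)")
    for g in circuit.gates:
        lines.append(f"gate {g.name} = {g.render()} @ {g.concentration:g} (* {g.role} *)")
    return "\n".join(lines) + "\n"


_DEF_RE = re.compile(r"^def (\S+?)(\^)? = (toehold|long) \((\w+)\)$")
_STRAND_RE = re.compile(r"^strand (\S+) = <(.*)> @ (\S+) \(\* (.*) \*\)$")
_GATE_RE = re.compile(r"^gate (\S+) = (.*) @ (\S+) \(\* (.*) \*\)$")


def parse_dsd_script(text: str) -> DSDCircuit:
    """Parse a script produced by :func:`export_dsd_script` (round trip)."""
    domains, strands, gates = [], [], []
    meta: dict = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("(*"):
            mobj = re.search(r"N=(\d+), m=(\d+)", line)
            if mobj:
                meta["N"], meta["m"] = int(mobj.group(1)), int(mobj.group(2))
            continue
        mobj = _DEF_RE.match(line)
        if mobj:
            name, caret, kind, family = mobj.groups()
            domains.append(Domain(name, kind, family))
            continue
        mobj = _STRAND_RE.match(line)
        if mobj:
            name, body, conc, role = mobj.groups()
            strands.append(Strand(name, tuple(body.split()), role, float(conc)))
            continue
        mobj = _GATE_RE.match(line)
        if mobj:
            name, struct, conc, role = mobj.groups()
            gates.append(GateComplex(name, parse_structure(struct), role,
                                     float(conc)))
            continue
        raise ValueError(f"unparseable script line: {line!r}")
    c = DSDCircuit(N=meta.get("N", 0), m=meta.get("m", 0), domains=domains,
                   strands=strands, gates=gates)
    c.validate()
    return c
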