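"""Reaction-network containers and builders for the chemical neuron (CN, c-CN).

The chemical neuron maps the elements of a spiking neuron onto molecular
abundances:

* input channel ``i``  -> input species ``A_i`` delivered as decaying boli
  (a reservoir of ``beta`` precursors ``I_i`` releasing at rate ``kappa``),
* synaptic weight      -> abundance of the channel-specific catalyst ``H_i``,
* internal state       -> abundance of the shared species ``B``,
* output / learning signal -> the fully occupied state ``C_m`` of a receptor
  chain with ``m`` cooperative binding sites for ``B``.

Weight update is Hebbian: ``A_i`` is converted into ``H_i`` only while the
learning signal ``C_m`` is present, i.e. only when input and output coincide.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "NeuronSpec",
    "GeneParams",
    "default_spec",
    "build_cn",
    "build_activation_chain",
    "build_ccn",
]


class InvalidSpecError(ValueError):
    """Raised when a neuron specification or network is structurally invalid."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A chemical species with an initial abundance.

    ``initial_count`` is an integer molecule count in stochastic mode and may
    be a non-negative real in concentration (ODE) mode; the engine does not
    convert units.
    """

    name: str
    compartment: str = "bulk"
    initial_count: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_count < 0:
            raise InvalidSpecError(f"initial_count of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction with at most two reactants.

    ``modifier`` optionally names a *virtual* catalyst whose abundance the
    simulation engine computes on the fly (used by the Hill shortcut for the
    activation chain); plain simulations ignore it only if it is ``None``.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    label: str = ""
    modifier: str | None = None

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise InvalidSpecError(f"rate_constant of {self.label!r} must be >= 0")
        if len(self.reactants) > 2:
            raise InvalidSpecError(
                f"reaction {self.label!r}: at most bimolecular reactant multisets "
                "are supported (SSA propensities)"
            )
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))


@dataclass
class ReactionNetwork:
    """A closed set of species and mass-action reactions."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- bookkeeping --------------------------------------------------------
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names().index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def has_species(self, name: str) -> bool:
        return name in self.species_names()

    def initial_counts(self) -> list[float]:
        return [s.initial_count for s in self.species]

    def validate(self) -> None:
        names = self.species_names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidSpecError(f"duplicate species names: {dupes}")
        known = set(names)
        for r in self.reactions:
            for name in (*r.reactants, *r.products):
                if name not in known:
                    raise InvalidSpecError(
                        f"reaction {r.label!r} references unknown species {name!r}"
                    )

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        """Human-readable listing, one species / reaction per line."""
        out = io.StringIO()
        for s in self.species:
            out.write(f"species {s.name} @ {s.initial_count:g} in {s.compartment}\n")
        for r in self.reactions:
            lhs = " + ".join(r.reactants) if r.reactants else "0"
            rhs = " + ".join(r.products) if r.products else "0"
            mod = f" !{r.modifier}" if r.modifier else ""
            out.write(f"{lhs} -> {rhs} @ {r.rate_constant:.12g}{mod}  # {r.label}\n")
        return out.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ReactionNetwork":
        net = cls()
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("species "):
                body = line[len("species "):]
                name, rest = body.split(" @ ", 1)
                count_s, comp = rest.split(" in ", 1)
                net.species.append(Species(name.strip(), comp.strip(), float(count_s)))
                continue
            label = ""
            if "#" in line:
                line, label = line.split("#", 1)
                label = label.strip()
            lhs, rest = line.split("->", 1)
            rhs, rate_s = rest.split("@", 1)
            rate_s = rate_s.strip()
            modifier = None
            if "!" in rate_s:
                rate_s, modifier = rate_s.split("!", 1)
                modifier = modifier.strip()
            reactants = tuple(t for t in (x.strip() for x in lhs.split("+")) if t and t != "0")
            products = tuple(t for t in (x.strip() for x in rhs.split("+")) if t and t != "0")
            net.reactions.append(
                Reaction(reactants, products, float(rate_s), label, modifier)
            )
        net.validate()
        return net

    def to_json(self) -> str:
        doc = {
            "species": [asdict(s) for s in self.species],
            "reactions": [asdict(r) for r in self.reactions],
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        doc = json.loads(text)
        net = cls(
            species=[Species(**s) for s in doc["species"]],
            reactions=[
                Reaction(
                    tuple(r["reactants"]), tuple(r["products"]),
                    r["rate_constant"], r.get("label", ""), r.get("modifier"),
                )
                for r in doc["reactions"]
            ],
            metadata=doc.get("metadata", {}),
        )
        net.validate()
        return net


# ---------------------------------------------------------------------------
# Neuron specification
# ---------------------------------------------------------------------------

_DEF = {
    # Calibrated "default-cn" parameter set; mirrored in data/default_cn.yaml.
    # Time is dimensionless; abundances are molecule counts.
    "N": 2,
    "m": 1,
    "beta": 50,
    "kappa": 100.0,
    "k_AB": 5.0,
    "k_BA": 5.0e-3,
    "k_cat": 1.0,
    "k_cat_rev": 1.0e-3,
    "k_learn": 2.0,
    "k_learn_rev": 2.0e-3,
    "k_plus": 10.0,
    "k_minus": 1000.0,
    "coop_factor": 0.01,
    "d_H": 0.01,
    "d_B": 20.0,
    "E_total": 40,
}


@dataclass
class NeuronSpec:
    """All tunable parameters of the chemical neuron in one validated record.

    Parameters
    ----------
    N : number of input channels.
    m : activation-chain length ("nonlinearity"); the maximal attainable Hill
        exponent of the activation function.
    beta : bolus size (precursor molecules per input spike).
    kappa : precursor release rate I_i -> A_i (1/time).
    k_AB, k_BA : uncatalyzed A_i <-> B conversion rates.
    k_cat, k_cat_rev : H_i-catalyzed A_i <-> B conversion rates (per catalyst
        molecule).
    k_learn, k_learn_rev : learning-signal-catalyzed A_i <-> H_i rates.
    k_plus, k_minus : B binding / unbinding rates on the receptor chain; the
        half-occupancy threshold is ``theta = k_minus / k_plus``.
    coop_factor : cooperativity factor rho in (0, 1]; the final unbinding step
        C_m -> C_{m-1} + B runs at ``rho * k_minus`` (slow unbinding from the
        fully occupied state gives ultrasensitivity).
    d_H, d_B : leak (decay) rates of weights and internal state.
    E_total : receptor copies (initial count of the empty chain state C_0).
    H_init : per-channel initial weights (defaults to zeros).
    """

    N: int = _DEF["N"]
    m: int = _DEF["m"]
    beta: int = _DEF["beta"]
    kappa: float = _DEF["kappa"]
    k_AB: float = _DEF["k_AB"]
    k_BA: float = _DEF["k_BA"]
    k_cat: float = _DEF["k_cat"]
    k_cat_rev: float = _DEF["k_cat_rev"]
    k_learn: float = _DEF["k_learn"]
    k_learn_rev: float = _DEF["k_learn_rev"]
    k_plus: float = _DEF["k_plus"]
    k_minus: float = _DEF["k_minus"]
    coop_factor: float = _DEF["coop_factor"]
    d_H: float = _DEF["d_H"]
    d_B: float = _DEF["d_B"]
    E_total: int = _DEF["E_total"]
    H_init: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InvalidSpecError("N must be a positive integer")
        if self.m < 1:
            raise InvalidSpecError("m must be a positive integer")
        if self.beta < 1:
            raise InvalidSpecError("beta must be a positive integer")
        if self.kappa <= 0 or self.k_plus <= 0 or self.k_minus <= 0:
            raise InvalidSpecError("kappa, k_plus and k_minus must be > 0")
        if not (0 < self.coop_factor <= 1):
            raise InvalidSpecError("coop_factor must lie in (0, 1]")
        if self.E_total < 1:
            raise InvalidSpecError("E_total must be a positive integer")
        for name in ("k_AB", "k_BA", "k_cat", "k_cat_rev", "k_learn",
                     "k_learn_rev", "d_H", "d_B"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if self.H_init is None:
            self.H_init = tuple(0 for _ in range(self.N))
        else:
            self.H_init = tuple(int(h) for h in self.H_init)
            if len(self.H_init) != self.N:
                raise InvalidSpecError("H_init must have length N")
            if any(h < 0 for h in self.H_init):
                raise InvalidSpecError("H_init entries must be >= 0")

    @property
    def threshold(self) -> float:
        """Half-occupancy level of a single chain site, theta = k_minus/k_plus."""
        return self.k_minus / self.k_plus

    def with_(self, **kw) -> "NeuronSpec":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        if "N" in kw and "H_init" not in kw:
            d["H_init"] = None
        d.update(kw)
        return NeuronSpec(**d)

    # -- config I/O ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["H_init"] = list(self.H_init)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NeuronSpec":
        d = dict(d)
        if d.get("H_init") is not None:
            d["H_init"] = tuple(d["H_init"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NeuronSpec":
        return cls.from_dict(yaml.safe_load(text))


def default_spec(**overrides) -> NeuronSpec:
    """The calibrated default parameter set shipped with the package."""
    from importlib.resources import files

    text = files("chemneuron").joinpath("data/default_cn.yaml").read_text()
    return NeuronSpec.from_yaml(text).with_(**overrides)


# ---------------------------------------------------------------------------
# CN builder
# ---------------------------------------------------------------------------

def build_activation_chain(m: int, k_plus: float, k_minus: float,
                           rho: float) -> list[Reaction]:
    """Binding/unbinding ladder C_0 ... C_m for a receptor with ``m`` sites.

    Returns ``2 m`` reactions; the single unbinding step out of the fully
    occupied state ``C_m`` runs at ``rho * k_minus`` (cooperative slow-down).
    """
    if m < 1:
        raise InvalidSpecError("chain length m must be >= 1")
    if k_plus <= 0 or k_minus <= 0:
        raise InvalidSpecError("k_plus and k_minus must be > 0")
    if not (0 < rho <= 1):
        raise InvalidSpecError("rho must lie in (0, 1]")
    rxns: list[Reaction] = []
    for j in range(m):
        rxns.append(Reaction((f"C_{j}", "B"), (f"C_{j + 1}",),
                             k_plus, f"chain_bind_{j}"))
        k_off = rho * k_minus if j + 1 == m else k_minus
        rxns.append(Reaction((f"C_{j + 1}",), (f"C_{j}", "B"),
                             k_off, f"chain_unbind_{j + 1}"))
    return rxns


def build_cn(spec: NeuronSpec, activation: str = "chain") -> ReactionNetwork:
    """Construct the minimal chemical-neuron network.

    Per channel i: bolus release I_i -> A_i; uncatalyzed and H_i-catalyzed
    conversion A_i <-> B; learning A_i <-> H_i catalyzed by the fully occupied
    chain state C_m; weight leak H_i -> 0.  Globally: state leak B -> 0 and
    the activation chain C_0 ... C_m.

    With ``activation="hill"`` the explicit chain is omitted and the learning
    reactions reference the virtual catalyst ``"E_active"`` instead; such a
    network must be simulated with the engine's Hill shortcut.
    """
    if activation not in ("chain", "hill"):
        raise ValueError("activation must be 'chain' or 'hill'")
    net = ReactionNetwork(metadata={
        "model": "cn", "N": spec.N, "m": spec.m, "activation": activation,
    })
    for i in range(1, spec.N + 1):
        net.species.append(Species(f"I_{i}"))
        net.species.append(Species(f"A_{i}"))
        net.species.append(Species(f"H_{i}", initial_count=spec.H_init[i - 1]))
    net.species.append(Species("B"))

    learn_cat = ("C_" + str(spec.m),) if activation == "chain" else ()
    modifier = None if activation == "chain" else "E_active"
    for i in range(1, spec.N + 1):
        A, H, I = f"A_{i}", f"H_{i}", f"I_{i}"
        net.reactions.append(Reaction((I,), (A,), spec.kappa, f"input_{i}"))
        net.reactions.append(Reaction((A,), ("B",), spec.k_AB, f"convert_{i}"))
        net.reactions.append(Reaction(("B",), (A,), spec.k_BA, f"convert_{i}_rev"))
        net.reactions.append(Reaction((A, H), ("B", H), spec.k_cat, f"catalyzed_{i}"))
        net.reactions.append(Reaction(("B", H), (A, H), spec.k_cat_rev,
                                      f"catalyzed_{i}_rev"))
        net.reactions.append(Reaction((A, *learn_cat), (H, *learn_cat),
                                      spec.k_learn, f"learn_{i}", modifier))
        net.reactions.append(Reaction((H, *learn_cat), (A, *learn_cat),
                                      spec.k_learn_rev, f"learn_{i}_rev", modifier))
        net.reactions.append(Reaction((H,), (), spec.d_H, f"leak_H_{i}"))
    net.reactions.append(Reaction(("B",), (), spec.d_B, "leak_B"))

    if activation == "chain":
        net.species.append(Species("C_0", initial_count=spec.E_total))
        for j in range(1, spec.m + 1):
            net.species.append(Species(f"C_{j}"))
        net.reactions.extend(
            build_activation_chain(spec.m, spec.k_plus, spec.k_minus,
                                   spec.coop_factor))
    net.validate()
    return net


# ---------------------------------------------------------------------------
# c-CN builder
# ---------------------------------------------------------------------------

@dataclass
class GeneParams:
    """Gene-expression kinetics for the compartmentalized neuron.

    Each compartment carries a gene ``h_0`` whose promoter is activated by the
    activated input form ``A*``; the expressed product ``H`` is a transporter
    exporting ``A`` to the bulk (where it is called ``B``).
    """

    promoter_bind: float = 0.1
    promoter_unbind: float = 1.0
    expression_rate: float = 50.0
    leak_expression_rate: float = 0.05
    activation_rate: float = 2.0       # A + C_m -> A* + C_m, per catalyst
    deactivation_rate: float = 10.0    # A* -> A (short-lived activated form)
    e_per_compartment: int | None = None  # default: spec.E_total per compartment

    def __post_init__(self) -> None:
        for name in ("promoter_bind", "promoter_unbind", "expression_rate",
                     "leak_expression_rate", "activation_rate",
                     "deactivation_rate"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")


def build_ccn(spec: NeuronSpec, gene_params: GeneParams | None = None,
              activation: str = "chain") -> ReactionNetwork:
    """Construct the compartmentalized neuron (c-CN).

    Channel index becomes a compartment: ``A``, ``A*``, the gene ``h_0``/``h``,
    the transporter ``H`` and the receptor chain live in compartment ``i``;
    the exported input is the single bulk species ``B``.  Every compartment
    carries its own receptor chain (minimum E copy number is N), all driven by
    the shared bulk B.
    """
    if gene_params is None:
        gene_params = GeneParams()
    if activation not in ("chain", "hill"):
        raise ValueError("activation must be 'chain' or 'hill'")
    gp = gene_params
    e_per = gp.e_per_compartment if gp.e_per_compartment is not None else spec.E_total

    net = ReactionNetwork(metadata={
        "model": "ccn", "N": spec.N, "m": spec.m, "activation": activation,
        "e_per_compartment": e_per,
    })
    net.species.append(Species("B"))
    for i in range(1, spec.N + 1):
        c = str(i)
        net.species.append(Species(f"I_{i}", c))
        net.species.append(Species(f"A_{i}", c))
        net.species.append(Species(f"Astar_{i}", c))
        net.species.append(Species(f"h0_{i}", c, initial_count=1))
        net.species.append(Species(f"h_{i}", c))
        net.species.append(Species(f"H_{i}", c, initial_count=spec.H_init[i - 1]))
        if activation == "chain":
            net.species.append(Species(f"C_0_{i}", c, initial_count=e_per))
            for j in range(1, spec.m + 1):
                net.species.append(Species(f"C_{j}_{i}", c))

    for i in range(1, spec.N + 1):
        A, As, H = f"A_{i}", f"Astar_{i}", f"H_{i}"
        h0, h = f"h0_{i}", f"h_{i}"
        Cm = (f"C_{spec.m}_{i}",) if activation == "chain" else ()
        modifier = None if activation == "chain" else f"E_active_{i}"
        net.reactions.append(Reaction((f"I_{i}",), (A,), spec.kappa, f"input_{i}"))
        # activation of A by the occupied receptor (the learning signal)
        net.reactions.append(Reaction((A, *Cm), (As, *Cm), gp.activation_rate,
                                      f"activate_{i}", modifier))
        net.reactions.append(Reaction((As,), (A,), gp.deactivation_rate,
                                      f"deactivate_{i}"))
        # promoter binding and gene expression
        net.reactions.append(Reaction((h0, As), (h,), gp.promoter_bind,
                                      f"promoter_bind_{i}"))
        net.reactions.append(Reaction((h,), (h0, As), gp.promoter_unbind,
                                      f"promoter_unbind_{i}"))
        net.reactions.append(Reaction((h,), (h, H), gp.expression_rate,
                                      f"express_{i}"))
        net.reactions.append(Reaction((h0,), (h0, H), gp.leak_expression_rate,
                                      f"express_leak_{i}"))
        # export of A to the bulk: uncatalyzed and transporter-mediated
        net.reactions.append(Reaction((A,), ("B",), spec.k_AB, f"export_{i}"))
        net.reactions.append(Reaction((A, H), (H, "B"), spec.k_cat,
                                      f"transport_{i}"))
        net.reactions.append(Reaction((H,), (), spec.d_H, f"leak_H_{i}"))
        if activation == "chain":
            for j in range(spec.m):
                net.reactions.append(
                    Reaction((f"C_{j}_{i}", "B"), (f"C_{j + 1}_{i}",),
                             spec.k_plus, f"chain_bind_{j}_{i}"))
                k_off = (spec.coop_factor * spec.k_minus
                         if j + 1 == spec.m else spec.k_minus)
                net.reactions.append(
                    Reaction((f"C_{j + 1}_{i}",), (f"C_{j}_{i}", "B"),
                             k_off, f"chain_unbind_{j + 1}_{i}"))
    net.reactions.append(Reaction(("B",), (), spec.d_B, "leak_B"))
    net.validate()
    return net
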