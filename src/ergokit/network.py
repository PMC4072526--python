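"""Reaction-network data model and plain-text (.rxn) parser/writer.

A stochastic chemical reaction network consists of ``d`` species
``S_1 ... S_d`` interacting through ``K`` reaction channels.  Channel ``k``
is described by a stoichiometric vector ``zeta_k`` (the net integer change
in the species counts when the channel fires) and a propensity function
``lambda_k(x)`` giving its firing rate in state ``x``.  The package
supports three propensity kinds:

``mass_action``
    Stochastic mass-action kinetics.  A channel with reactant multiset
    ``{i: m_i}`` and rate constant ``kappa`` has propensity
    ``kappa * prod_i binom(x_i, m_i)`` -- the falling-factorial convention
    of the chemical master equation (e.g. ``kappa * x * (x-1) / 2`` for a
    homodimerization ``2 S_i -> ...``).  Orders up to 3 are accepted so
    that trimolecular models such as Schloegl's can be expressed.

``bounded_function``
    An arbitrary nonnegative propensity known only through a finite
    supremum ``sup_bound`` (e.g. a Hill-repressed transcription rate).
    Certificate computations use only the supremum; simulation requires a
    concrete closed form via ``eval_hint``.

``scaled_bounded``
    A propensity of the form ``g(x) * x_j`` with ``g`` nonnegative and
    bounded by ``sup_bound`` (e.g. saturating degradation
    ``a_k * y * x / (x + K)``, bounded per molecule of the scaling
    species ``y``).  Certificates use the linear envelope
    ``sup_bound * x_j``; simulation again requires ``eval_hint``.

The line-oriented ``.rxn`` text format::

    # comment
    species: A, B, C
    param k1 = 10.0
    reaction R1: 2 A + B -> C @ ma(k1)
    reaction R2: -> M @ bounded(sup=5.0, hint="k1/(1+C^2)")
    reaction R3: A -> @ bounded(sup=1.7, per=B, hint="1.7*B*A/(A+1)")
    interval k1 = [0.5, 2.0]

An empty reactant side denotes a birth channel, an empty product side pure
consumption.  Species and reaction ordering is declaration order
everywhere; all matrices produced by the package follow it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "PropensitySpec",
    "Reaction",
    "ReactionNetwork",
    "ParseError",
    "parse_network",
    "write_network",
    "stoichiometry_matrix",
    "bimolecular_stoichiometry",
]

MASS_ACTION = "mass_action"
BOUNDED = "bounded_function"
SCALED_BOUNDED = "scaled_bounded"


class ParseError(ValueError):
    """Raised when a .rxn document is malformed; carries the line number."""


@dataclass(frozen=True)
class Species:
    name: str
    index: int


@dataclass
class PropensitySpec:
    """Propensity description of a single reaction channel."""

    kind: str = MASS_ACTION
    rate_constant: float = 0.0
    reactant_multiset: dict[str, int] = field(default_factory=dict)
    sup_bound: float | None = None
    eval_hint: str | None = None
    scale_species: str | None = None
    rate_symbol: str | None = None  # parameter name, kept for round-tripping

    @property
    def order(self) -> int:
        return sum(self.reactant_multiset.values())

    def validate(self) -> None:
        if self.kind == MASS_ACTION:
            if self.rate_constant < 0:
                raise ValueError("negative mass-action rate constant")
            if self.order > 3:
                raise ValueError("mass-action order > 3 is not supported")
        elif self.kind in (BOUNDED, SCALED_BOUNDED):
            if self.sup_bound is None or not math.isfinite(self.sup_bound):
                raise ValueError(f"{self.kind} propensity requires a finite sup bound")
            if self.sup_bound < 0:
                raise ValueError("sup bound must be nonnegative")
            if self.kind == SCALED_BOUNDED and self.scale_species is None:
                raise ValueError("scaled_bounded propensity requires a scale species")
        else:
            raise ValueError(f"unknown propensity kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "rate_constant": self.rate_constant,
            "reactants": dict(sorted(self.reactant_multiset.items())),
            "sup_bound": self.sup_bound,
            "eval_hint": self.eval_hint,
            "scale_species": self.scale_species,
        }


@dataclass
class Reaction:
    label: str
    zeta: np.ndarray  # length-d integer vector, declaration order
    propensity: PropensitySpec

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "zeta": [int(z) for z in self.zeta],
            "propensity": self.propensity.to_dict(),
        }


class ReactionNetwork:
    """Ordered species + ordered reaction channels, with classification.

    ``class_tag`` is derived from the mass-action orders present:
    ``unimolecular`` (all orders <= 1; bounded propensities allowed),
    ``bimolecular`` (an order-2 channel present, none above 2) or
    ``general_mass_action`` (an order-3 channel present).  Networks that
    only make sense with an explicit tag (e.g. bounded kinetics outside
    the unimolecular template) may set ``class_tag`` directly.
    """

    def __init__(
        self,
        species: list[str],
        reactions: list[Reaction] | None = None,
        rate_intervals: dict[str, tuple[float, float]] | None = None,
        params: dict[str, float] | None = None,
        class_tag: str | None = None,
        name: str | None = None,
    ):
        if len(set(species)) != len(species):
            raise ValueError("species names must be unique")
        self.species = list(species)
        self.reactions: list[Reaction] = []
        self.rate_intervals = dict(rate_intervals or {})
        self.params = dict(params or {})
        self._class_tag = class_tag
        self.name = name
        for r in reactions or []:
            self._check_reaction(r)
            self.reactions.append(r)

    # -- construction -------------------------------------------------

    @property
    def d(self) -> int:
        return len(self.species)

    @property
    def K(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def _check_reaction(self, r: Reaction) -> None:
        r.propensity.validate()
        zeta = np.asarray(r.zeta, dtype=int)
        if zeta.shape != (self.d,):
            raise ValueError(f"reaction {r.label}: zeta has wrong length")
        if not zeta.any() and r.propensity.kind == MASS_ACTION:
            raise ValueError(f"reaction {r.label}: no-op reaction (zeta = 0)")
        for name, mult in r.propensity.reactant_multiset.items():
            i = self.species_index(name)
            if zeta[i] < -mult:
                raise ValueError(
                    f"reaction {r.label}: consumes more {name} than its "
                    f"reactant multiplicity {mult}"
                )
        # a species may only be consumed if it appears as a reactant
        for i, z in enumerate(zeta):
            if z < 0 and self.species[i] not in r.propensity.reactant_multiset:
                raise ValueError(
                    f"reaction {r.label}: consumes {self.species[i]} which is "
                    "not a declared reactant"
                )
        r.zeta = zeta

    def add_reaction(
        self,
        label: str,
        reactants: dict[str, int],
        products: dict[str, int],
        rate: float | None = None,
        *,
        kind: str = MASS_ACTION,
        sup: float | None = None,
        hint: str | None = None,
        per: str | None = None,
        rate_symbol: str | None = None,
    ) -> Reaction:
        """Convenience builder from reactant/product multisets."""
        zeta = np.zeros(self.d, dtype=int)
        for name, m in reactants.items():
            zeta[self.species_index(name)] -= m
        for name, m in products.items():
            zeta[self.species_index(name)] += m
        spec = PropensitySpec(
            kind=kind,
            rate_constant=float(rate) if rate is not None else 0.0,
            reactant_multiset=dict(reactants),
            sup_bound=sup,
            eval_hint=hint,
            scale_species=per,
            rate_symbol=rate_symbol,
        )
        rxn = Reaction(label=label, zeta=zeta, propensity=spec)
        self._check_reaction(rxn)
        self.reactions.append(rxn)
        return rxn

    # -- classification ------------------------------------------------

    @property
    def class_tag(self) -> str:
        if self._class_tag is not None:
            return self._class_tag
        max_order = 0
        for r in self.reactions:
            if r.propensity.kind == MASS_ACTION:
                max_order = max(max_order, r.propensity.order)
        if max_order >= 3:
            return "general_mass_action"
        if max_order == 2:
            return "bimolecular"
        return "unimolecular"

    @class_tag.setter
    def class_tag(self, value: str | None) -> None:
        self._class_tag = value

    def mass_action_orders(self) -> list[int | None]:
        """Per-reaction order; None for non-mass-action channels."""
        return [
            r.propensity.order if r.propensity.kind == MASS_ACTION else None
            for r in self.reactions
        ]

    def has_bounded(self) -> bool:
        return any(r.propensity.kind != MASS_ACTION for r in self.reactions)

    # -- matrices -------------------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        if not self.reactions:
            return np.zeros((self.d, 0), dtype=int)
        return np.stack([r.zeta for r in self.reactions], axis=1)

    def bimolecular_stoichiometry(self) -> np.ndarray:
        cols = [
            r.zeta
            for r in self.reactions
            if r.propensity.kind == MASS_ACTION and r.propensity.order == 2
        ]
        if not cols:
            return np.zeros((self.d, 0), dtype=int)
        return np.stack(cols, axis=1)

    # -- equality / serialization --------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": [r.to_dict() for r in self.reactions],
            "rate_intervals": {k: list(v) for k, v in sorted(self.rate_intervals.items())},
            "params": dict(sorted(self.params.items())),
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, ReactionNetwork) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        tag = self.name or "network"
        return f"<ReactionNetwork {tag}: {self.d} species, {self.K} reactions, {self.class_tag}>"


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """d x K integer matrix whose column k is zeta_k."""
    return net.stoichiometry_matrix()


def bimolecular_stoichiometry(net: ReactionNetwork) -> np.ndarray:
    """Restriction of the stoichiometry matrix to order-2 channels."""
    return net.bimolecular_stoichiometry()


# ---------------------------------------------------------------------------
# .rxn parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s*)?([A-Za-z_]\w*)$")


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    if not text:
        return {}
    side: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise ParseError(f"line {lineno}: cannot parse term {term.strip()!r}")
        mult = int(m.group(1) or 1)
        name = m.group(2)
        side[name] = side.get(name, 0) + mult
    return side


def _resolve_rate(token: str, params: dict[str, float], lineno: int) -> tuple[float, str | None]:
    token = token.strip()
    try:
        return float(token), None
    except ValueError:
        pass
    if token in params:
        return params[token], token
    raise ParseError(f"line {lineno}: unknown rate parameter {token!r}")


_KV_RE = re.compile(r"(\w+)\s*=\s*(\"[^\"]*\"|[^,]+)")


def _parse_propensity(text: str, params: dict[str, float], lineno: int):
    text = text.strip()
    m = re.match(r"^(ma|bounded)\s*\((.*)\)$", text, re.S)
    if not m:
        raise ParseError(f"line {lineno}: cannot parse propensity {text!r}")
    head, body = m.group(1), m.group(2).strip()
    if head == "ma":
        rate, symbol = _resolve_rate(body, params, lineno)
        if rate < 0:
            raise ParseError(f"line {lineno}: negative rate")
        return {"kind": MASS_ACTION, "rate": rate, "symbol": symbol}
    kv = {k: v.strip() for k, v in _KV_RE.findall(body)}
    if "sup" not in kv:
        raise ParseError(f"line {lineno}: bounded propensity requires sup=")
    sup, symbol = _resolve_rate(kv["sup"], params, lineno)
    hint = kv.get("hint")
    if hint is not None:
        hint = hint.strip('"')
    return {
        "kind": SCALED_BOUNDED if "per" in kv else BOUNDED,
        "sup": sup,
        "hint": hint,
        "per": kv.get("per"),
        "symbol": symbol,
    }


def parse_network(text: str, name: str | None = None) -> ReactionNetwork:
    """Parse a .rxn document into a :class:`ReactionNetwork`.

    Species order and reaction order follow declaration order.  Errors
    name the offending line.
    """
    species: list[str] = []
    params: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}
    pending: list[tuple[int, str, str, str, str]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species:"):
            for nm in line[len("species:"):].split(","):
                nm = nm.strip()
                if not nm:
                    continue
                if not re.match(r"^[A-Za-z_]\w*$", nm):
                    raise ParseError(f"line {lineno}: bad species name {nm!r}")
                if nm in species:
                    raise ParseError(f"line {lineno}: duplicate species {nm!r}")
                species.append(nm)
        elif line.startswith("param"):
            m = re.match(r"^param\s+(\w+)\s*=\s*(\S+)$", line)
            if not m:
                raise ParseError(f"line {lineno}: cannot parse param line")
            params[m.group(1)] = float(m.group(2))
        elif line.startswith("interval"):
            m = re.match(r"^interval\s+(\w+)\s*=\s*\[([^,\]]+),([^,\]]+)\]$", line)
            if not m:
                raise ParseError(f"line {lineno}: cannot parse interval line")
            lo, hi = float(m.group(2)), float(m.group(3))
            if not (0 <= lo <= hi):
                raise ParseError(f"line {lineno}: invalid interval [{lo}, {hi}]")
            intervals[m.group(1)] = (lo, hi)
        elif line.startswith("reaction"):
            m = re.match(r"^reaction\s+(\w+)\s*:\s*(.*?)->(.*?)@(.*)$", line)
            if not m:
                raise ParseError(f"line {lineno}: cannot parse reaction line")
            pending.append((lineno, m.group(1), m.group(2), m.group(3), m.group(4)))
        else:
            raise ParseError(f"line {lineno}: unrecognized directive {line!r}")

    net = ReactionNetwork(species, params=params, name=name)
    for lineno, label, lhs, rhs, prop_text in pending:
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        for nm in list(reactants) + list(products):
            if nm not in species:
                raise ParseError(f"line {lineno}: unknown species {nm!r} in reaction {label}")
        spec = _parse_propensity(prop_text, params, lineno)
        try:
            if spec["kind"] == MASS_ACTION:
                net.add_reaction(label, reactants, products, spec["rate"],
                                 rate_symbol=spec["symbol"])
            else:
                if spec.get("per") is not None and spec["per"] not in species:
                    raise ParseError(
                        f"line {lineno}: unknown scale species {spec['per']!r}")
                net.add_reaction(
                    label, reactants, products,
                    kind=spec["kind"], sup=spec["sup"], hint=spec["hint"],
                    per=spec.get("per"), rate_symbol=spec["symbol"],
                )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc

    # attach per-reaction rate intervals derived from parameter intervals
    for r in net.reactions:
        sym = r.propensity.rate_symbol
        if sym is not None and sym in intervals:
            net.rate_intervals[r.label] = intervals[sym]
    net.params = params
    net._param_intervals = dict(intervals)
    return net


def _format_side(side: dict[str, int]) -> str:
    terms = []
    for name, mult in side.items():
        terms.append(name if mult == 1 else f"{mult} {name}")
    return " + ".join(terms)


def write_network(net: ReactionNetwork) -> str:
    """Serialize a network to .rxn text; inverse of :func:`parse_network`."""
    lines = []
    if net.species:
        lines.append("species: " + ", ".join(net.species))
    for sym, val in net.params.items():
        lines.append(f"param {sym} = {val!r}")
    for r in net.reactions:
        reactants = dict(r.propensity.reactant_multiset)
        products: dict[str, int] = {}
        for i, z in enumerate(r.zeta):
            net_prod = z + reactants.get(net.species[i], 0)
            if net_prod > 0:
                products[net.species[i]] = int(net_prod)
            elif net_prod < 0:  # pragma: no cover - excluded by invariants
                raise ValueError("inconsistent reaction")
        p = r.propensity
        if p.kind == MASS_ACTION:
            rate = p.rate_symbol if p.rate_symbol else repr(p.rate_constant)
            prop = f"ma({rate})"
        else:
            sup = p.rate_symbol if p.rate_symbol else repr(p.sup_bound)
            parts = [f"sup={sup}"]
            if p.scale_species:
                parts.append(f"per={p.scale_species}")
            if p.eval_hint:
                parts.append(f'hint="{p.eval_hint}"')
            prop = "bounded(" + ", ".join(parts) + ")"
        lines.append(
            f"reaction {r.label}: {_format_side(reactants)} -> "
            f"{_format_side(products)} @ {prop}"
        )
    intervals = getattr(net, "_param_intervals", None)
    if intervals:
        for sym, (lo, hi) in intervals.items():
            lines.append(f"interval {sym} = [{lo!r}, {hi!r}]")
    else:
        for label, (lo, hi) in net.rate_intervals.items():
            r = next(x for x in net.reactions if x.label == label)
            if r.propensity.rate_symbol:
                lines.append(f"interval {r.propensity.rate_symbol} = [{lo!r}, {hi!r}]")
    return "\n".join(lines) + "\n"
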