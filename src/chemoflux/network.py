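"""Atom-mapped metabolic network model and free-flux parameterization.

A network is a set of metabolite pools (balanced intracellular pools plus
non-balanced extracellular input/output pools) connected by reactions that
carry per-carbon atom transitions. Fluxes are parameterized in the net /
exchange convention: every reaction has a signed net flux, bidirectional
reactions additionally carry a non-negative exchange flux, and

    forward  = max(net, 0) + exchange
    backward = max(-net, 0) + exchange.

Steady state requires the net stoichiometric balance of every balanced pool
to vanish. Biomass formation is represented by a set of unidirectional
drain reactions whose rates are tied to the growth rate through fixed
composition coefficients (micromol per g cell dry weight), so a single
growth-rate parameter mu scales the whole biomass demand.

The free-flux basis is obtained by eliminating the balance and drain-tie
constraints: any assignment of the remaining free net fluxes (plus the free
exchange fluxes of bidirectional reactions) yields a full steady-state flux
distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml


class NetworkError(ValueError):
    """Raised for malformed network documents or infeasible flux queries."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    role: str = "balanced"  # balanced | input | output
    symmetric: bool = False

    def __post_init__(self):
        if self.role not in ("balanced", "input", "output"):
            raise NetworkError(f"{self.id}: unknown role {self.role!r}")
        if self.n_carbons < 0:
            raise NetworkError(f"{self.id}: negative carbon count")


@dataclass(frozen=True)
class Reaction:
    """One reaction with its carbon atom transitions.

    ``educts`` / ``products`` are tuples of (metabolite id, atom letters).
    The letter string assigns one lowercase letter per carbon position;
    letters establish the educt-carbon -> product-carbon bijection. Drain
    reactions into a carbon-free sink pool may leave educt carbons
    unassigned on the product side.
    """

    id: str
    educts: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    bidirectional: bool = False
    exchange_fixed: float | None = None
    variant_weight: float = 1.0
    parent: str | None = None
    nadph: int = 0  # moles NADPH produced (+) or consumed (-) per unit flux

    @property
    def is_drain(self) -> bool:
        return any(letters == "" for _, letters in self.products)

    def stoichiometry(self) -> dict[str, float]:
        """Net stoichiometric coefficients (products minus educts)."""
        st: dict[str, float] = {}
        for met, _ in self.educts:
            st[met] = st.get(met, 0.0) - 1.0
        for met, _ in self.products:
            st[met] = st.get(met, 0.0) + 1.0
        return st


_TERM = re.compile(r"^\s*([A-Za-z0-9_]+)\s*(?:#([a-z]*))?\s*$")


def _parse_side(side: str, rxn_id: str) -> tuple[tuple[str, str], ...]:
    terms = []
    for raw in side.split("+"):
        m = _TERM.match(raw)
        if not m:
            raise NetworkError(f"reaction {rxn_id}: cannot parse term {raw!r}")
        terms.append((m.group(1), m.group(2) or ""))
    return tuple(terms)


def parse_equation(rxn_id: str, equation: str) -> tuple[tuple, tuple]:
    if "->" not in equation:
        raise NetworkError(f"reaction {rxn_id}: missing '->'")
    lhs, rhs = equation.split("->", 1)
    return _parse_side(lhs, rxn_id), _parse_side(rhs, rxn_id)


@dataclass
class NetworkModel:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    biomass_demand: dict[str, float] = field(default_factory=dict)
    nadph_coefficient: float = 14849.0  # micromol NADPH per g CDW
    name: str = "network"

    # -- lookups ---------------------------------------------------------
    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def balanced(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "balanced"]

    @property
    def nonbalanced(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role != "balanced"]

    @property
    def bidirectional_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.bidirectional]

    @property
    def free_exchange_ids(self) -> list[str]:
        return [
            r.id
            for r in self.reactions
            if r.bidirectional and r.exchange_fixed is None
        ]

    def stoichiometric_matrix(self, balanced_only: bool = True) -> tuple[np.ndarray, list[str]]:
        pools = self.balanced if balanced_only else list(self.metabolites)
        pos = {p: i for i, p in enumerate(pools)}
        S = np.zeros((len(pools), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry().items():
                if met in pos:
                    S[pos[met], j] += coeff * r.variant_weight
        return S, pools

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for r in self.reactions:
            seen: dict[str, str] = {}
            for met, letters in r.educts + r.products:
                if met not in self.metabolites:
                    raise NetworkError(f"reaction {r.id}: undeclared metabolite {met}")
                n = self.metabolites[met].n_carbons
                if letters and len(letters) != n:
                    raise NetworkError(
                        f"reaction {r.id}: {met} has {n} carbons but atom map "
                        f"{letters!r} assigns {len(letters)}"
                    )
            educt_letters = "".join(l for _, l in r.educts)
            product_letters = "".join(l for _, l in r.products)
            if len(set(educt_letters)) != len(educt_letters):
                raise NetworkError(f"reaction {r.id}: duplicate educt atom letter")
            if len(set(product_letters)) != len(product_letters):
                raise NetworkError(f"reaction {r.id}: duplicate product atom letter")
            extra = set(product_letters) - set(educt_letters)
            if extra:
                raise NetworkError(
                    f"reaction {r.id}: product atoms {sorted(extra)} have no educt source"
                )
            missing = set(educt_letters) - set(product_letters)
            if missing and not r.is_drain:
                raise NetworkError(
                    f"reaction {r.id}: educt atoms {sorted(missing)} not conserved"
                )
            if r.bidirectional and r.is_drain:
                raise NetworkError(f"reaction {r.id}: drains must be unidirectional")
        # orphan balanced pools (no producing or consuming reaction)
        touched = set()
        for r in self.reactions:
            touched.update(met for met, _ in r.educts + r.products)
        orphans = [p for p in self.balanced if p not in touched]
        if orphans:
            raise NetworkError(f"balanced pools never touched by a reaction: {orphans}")

    def summary(self) -> dict:
        n_bi = len(self.bidirectional_ids)
        return {
            "name": self.name,
            "n_reactions": len(self.reactions),
            "n_bidirectional": n_bi,
            "n_unidirectional": len(self.reactions) - n_bi,
            "n_balanced_pools": len(self.balanced),
            "n_nonbalanced_pools": len(self.nonbalanced),
            "n_free_exchange": len(self.free_exchange_ids),
        }

    def summary_table(self) -> "pd.DataFrame":  # noqa: F821 - optional pandas
        import pandas as pd

        rows = []
        for r in self.reactions:
            rows.append(
                {
                    "reaction": r.id,
                    "direction": "<=>" if r.bidirectional else "=>",
                    "educts": " + ".join(m for m, _ in r.educts),
                    "products": " + ".join(m for m, _ in r.products),
                    "atom_map": "; ".join(
                        f"{m}#{l}" for m, l in r.educts + r.products if l
                    ),
                    "variant_weight": r.variant_weight,
                }
            )
        return pd.DataFrame(rows)


def load_network(document: str) -> NetworkModel:
    """Parse a YAML network document and validate it.

    The dialect has three top-level keys: ``metabolites`` (id, carbons,
    role, symmetric), ``reactions`` (id, equation with ``#letters`` atom
    maps, bidirectional, exchange_fixed, nadph) and optional
    ``biomass_demand`` (drain reaction id -> micromol per g CDW) plus
    ``nadph_coefficient``.
    """
    doc = yaml.safe_load(document)
    mets: dict[str, Metabolite] = {}
    for m in doc["metabolites"]:
        met = Metabolite(
            id=m["id"],
            n_carbons=int(m.get("carbons", 0)),
            role=m.get("role", "balanced"),
            symmetric=bool(m.get("symmetric", False)),
        )
        mets[met.id] = met
    reactions = []
    for r in doc["reactions"]:
        educts, products = parse_equation(r["id"], r["equation"])
        reactions.append(
            Reaction(
                id=r["id"],
                educts=educts,
                products=products,
                bidirectional=bool(r.get("bidirectional", False)),
                exchange_fixed=r.get("exchange_fixed"),
                nadph=int(r.get("nadph", 0)),
            )
        )
    model = NetworkModel(
        metabolites=mets,
        reactions=reactions,
        biomass_demand={k: float(v) for k, v in doc.get("biomass_demand", {}).items()},
        nadph_coefficient=float(doc.get("nadph_coefficient", 14849.0)),
        name=doc.get("name", "network"),
    )
    model.validate()
    return model


def load_bundled(name: str = "cglutamicum") -> NetworkModel:
    """Load a network shipped with the package (data/<name>.yaml)."""
    from importlib import resources

    text = resources.files("chemoflux.data").joinpath(f"{name}.yaml").read_text()
    return load_network(text)


# -- scrambling ----------------------------------------------------------

def _orientations(model: NetworkModel, rxn: Reaction):
    """All orientation variants of one reaction over its symmetric species."""
    sym_slots = [
        (side, i)
        for side in ("educts", "products")
        for i, (met, letters) in enumerate(getattr(rxn, side))
        if letters and model.metabolites[met].symmetric
    ]
    if not sym_slots:
        return [rxn]
    variants = []
    n = len(sym_slots)
    for mask in range(2 ** n):
        educts = list(rxn.educts)
        products = list(rxn.products)
        for k, (side, i) in enumerate(sym_slots):
            if mask >> k & 1:
                lst = educts if side == "educts" else products
                met, letters = lst[i]
                lst[i] = (met, letters[::-1])
        variants.append(
            replace(
                rxn,
                id=f"{rxn.id}__v{mask}",
                educts=tuple(educts),
                products=tuple(products),
                variant_weight=rxn.variant_weight / 2 ** n,
                parent=rxn.parent or rxn.id,
            )
        )
    return variants


def expand_scrambling(model: NetworkModel) -> NetworkModel:
    """Replace reactions touching C-symmetric pools by orientation variants.

    A rotationally symmetric metabolite (succinate, fumarate, meso-DAP) is
    indistinguishable from its reversed carbon order, so every reaction
    producing or consuming it is split into equally weighted variants whose
    atom maps are mirror images. Stoichiometry and pool balances are
    unchanged. Networks without symmetric species are returned as-is.
    """
    if not any(m.symmetric for m in model.metabolites.values()):
        return model
    expanded: list[Reaction] = []
    for r in model.reactions:
        expanded.extend(_orientations(model, r))
    out = replace(model, reactions=expanded)
    return out


# -- flux states ---------------------------------------------------------

@dataclass
class FluxState:
    """Net and exchange fluxes for every reaction of a model.

    ``net`` and ``exchange`` are aligned with ``model.reactions`` (parent
    reactions, before scrambling expansion). Units: micromol / gCDW / h;
    the growth rate ``mu`` (h^-1) scales the biomass drains.
    """

    model: NetworkModel
    net: np.ndarray
    exchange: np.ndarray
    mu: float = 0.0

    def __post_init__(self):
        self.net = np.asarray(self.net, dtype=float)
        self.exchange = np.asarray(self.exchange, dtype=float)
        if self.net.shape != (len(self.model.reactions),):
            raise NetworkError("net flux vector has wrong length")
        if np.any(self.exchange < -1e-12):
            raise NetworkError("negative exchange flux")

    @property
    def forward(self) -> np.ndarray:
        return np.maximum(self.net, 0.0) + self.exchange

    @property
    def backward(self) -> np.ndarray:
        return np.maximum(-self.net, 0.0) + self.exchange

    def net_of(self, rxn_id: str) -> float:
        return float(self.net[self.model.reaction_index[rxn_id]])

    def balance_residuals(self) -> np.ndarray:
        S, _ = self.model.stoichiometric_matrix()
        return S @ self.net

    def max_relative_residual(self, reference: float | None = None) -> float:
        res = np.abs(self.balance_residuals())
        ref = reference if reference else max(np.max(np.abs(self.net)), 1.0)
        return float(res.max() / ref)

    def feasible(self, tol: float = 1e-9) -> bool:
        uni = np.array([not r.bidirectional for r in self.model.reactions])
        scale = max(np.max(np.abs(self.net)), 1.0)
        return bool(
            np.all(self.net[uni] >= -tol * scale)
            and self.max_relative_residual() < 1e-6
        )


@dataclass
class FluxBasis:
    """Affine parameterization of the steady-state flux space.

    net = particular + kernel @ free_net, where ``particular`` solves the
    balance + drain-tie (+ any hard-fixed rate) constraints and ``kernel``
    spans their null space restricted to the chosen free reactions. The
    growth rate is carried as an extra coordinate (last column of the
    augmented system) so biomass drains stay tied to mu.
    """

    model: NetworkModel
    free_net: list[str]
    free_exchange: list[str]
    kernel: np.ndarray       # (n_reactions + 1, n_free_net) rows incl. mu
    particular: np.ndarray   # (n_reactions + 1,)
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free_net) + len(self.free_exchange)

    def realize(self, free_values, exchange_values=None, mu: float | None = None) -> FluxState:
        return realize_fluxes(self, free_values, exchange_values, mu)

    def extract_free(self, state: FluxState) -> np.ndarray:
        out = []
        for r in self.free_net:
            if r == "__mu__":
                out.append(state.mu)
            else:
                out.append(state.net_of(r))
        return np.array(out) if out else np.zeros(0)

    def extract_exchange(self, state: FluxState) -> np.ndarray:
        return np.array(
            [state.exchange[self.model.reaction_index[r]] for r in self.free_exchange]
        )


# preference order for free net fluxes: uptake / growth scales first, then
# the classic branch-point fluxes of central carbon metabolism.
_FREE_NET_PREFERENCE = [
    "pts", "pca_upt", "__mu__", "zwf", "pyc", "pck", "mez", "ppc", "icl",
    "odx", "pgi", "gnd",
]


def build_flux_basis(model: NetworkModel, fixed: dict[str, float] | None = None) -> FluxBasis:
    """Construct a deterministic free-flux basis.

    Constraints: steady-state balance of every balanced pool; each biomass
    drain tied to the growth-rate coordinate by its composition coefficient;
    optionally hard-fixed rates from ``fixed`` (reaction id -> value, plus
    the key ``"mu"`` for the growth rate). Free net fluxes are chosen
    greedily along a documented preference list (uptakes and growth first,
    then textbook branch points), falling back to reaction order; the
    choice maximizes rank at each step, so it is deterministic.
    """
    fixed = dict(fixed or {})
    n = len(model.reactions)
    S, _ = model.stoichiometric_matrix()
    rows = [np.hstack([S, np.zeros((S.shape[0], 1))])]
    rhs = [np.zeros(S.shape[0])]
    idx = model.reaction_index
    for rxn_id, coeff in model.biomass_demand.items():
        row = np.zeros(n + 1)
        row[idx[rxn_id]] = 1.0
        row[n] = -coeff
        rows.append(row[None, :])
        rhs.append(np.zeros(1))
    for key, value in fixed.items():
        row = np.zeros(n + 1)
        if key == "mu":
            row[n] = 1.0
        else:
            row[idx[key]] = 1.0
        rows.append(row[None, :])
        rhs.append(np.array([float(value)]))
    if not model.biomass_demand and "mu" not in fixed:
        # without drains the growth-rate coordinate is inert; pin it
        row = np.zeros(n + 1)
        row[n] = 1.0
        rows.append(row[None, :])
        rhs.append(np.zeros(1))
    A = np.vstack(rows)
    b = np.hstack(rhs)

    # consistency of the fixed constraints
    rank_A = np.linalg.matrix_rank(A)
    rank_Ab = np.linalg.matrix_rank(np.hstack([A, b[:, None]]))
    if rank_Ab > rank_A:
        raise NetworkError(
            "inconsistent fixed rates: constraints "
            f"{sorted(fixed)} conflict with the balance/drain structure"
        )

    particular, *_ = np.linalg.lstsq(A, b, rcond=None)
    # null space via SVD
    _, sv, vt = np.linalg.svd(A)
    tol = max(A.shape) * (sv[0] if sv.size else 1.0) * np.finfo(float).eps
    ns = vt[np.sum(sv > tol):].T  # (n+1, k)
    k = ns.shape[1]

    names = [r.id for r in model.reactions] + ["__mu__"]
    order = [c for c in _FREE_NET_PREFERENCE if c in names and c not in fixed]
    order += [c for c in names if c not in order and c not in fixed]
    chosen: list[int] = []
    basis_rows = np.zeros((0, k))
    for cand in order:
        if len(chosen) == k:
            break
        i = names.index(cand)
        trial = np.vstack([basis_rows, ns[i]])
        if np.linalg.matrix_rank(trial, tol=1e-10) > basis_rows.shape[0]:
            basis_rows = trial
            chosen.append(i)
    if len(chosen) != k:
        raise NetworkError("could not complete free-flux selection")
    # re-map kernel so free coordinates equal the chosen reaction fluxes
    M = ns[chosen, :]  # (k, k), invertible by construction
    kernel = ns @ np.linalg.inv(M)
    # make particular have zero value at the chosen free coordinates
    particular = particular - kernel @ particular[chosen]
    free_net = [names[i] for i in chosen]
    return FluxBasis(
        model=model,
        free_net=free_net,
        free_exchange=model.free_exchange_ids,
        kernel=kernel,
        particular=particular,
        fixed=fixed,
    )


def realize_fluxes(
    basis: FluxBasis,
    free_values,
    exchange_values=None,
    mu: float | None = None,
) -> FluxState:
    """Turn free net values (+ free exchange values) into a full FluxState.

    ``free_values`` follows ``basis.free_net`` order; if the growth rate is
    itself free it appears there as ``__mu__``. ``exchange_values`` follows
    ``basis.free_exchange``; omitted entries default to zero. Bidirectional
    reactions with a fixed exchange receive that value.
    """
    free_values = np.asarray(free_values, dtype=float)
    if free_values.shape != (len(basis.free_net),):
        raise NetworkError(
            f"expected {len(basis.free_net)} free net values, got {free_values.shape}"
        )
    if not np.all(np.isfinite(free_values)):
        raise NetworkError("non-finite free net value")
    vec = basis.particular + basis.kernel @ free_values
    model = basis.model
    n = len(model.reactions)
    net = vec[:n]
    mu_val = vec[n]
    if mu is not None and "mu" not in basis.fixed and "__mu__" not in basis.free_net:
        mu_val = mu
    exchange = np.zeros(n)
    if exchange_values is not None:
        exchange_values = np.asarray(exchange_values, dtype=float)
        if exchange_values.shape != (len(basis.free_exchange),):
            raise NetworkError("wrong number of exchange values")
        if np.any(exchange_values < 0):
            raise NetworkError("negative exchange flux")
        for r_id, x in zip(basis.free_exchange, exchange_values):
            exchange[model.reaction_index[r_id]] = x
    for r in model.reactions:
        if r.bidirectional and r.exchange_fixed is not None:
            exchange[model.reaction_index[r.id]] = r.exchange_fixed
    return FluxState(model=model, net=net, exchange=exchange, mu=float(mu_val))


def exchange_to_unit(x: np.ndarray, scale: float = 1000.0) -> np.ndarray:
    """Map raw exchange fluxes [0, inf) to the bounded optimizer variable [0, 1)."""
    x = np.asarray(x, dtype=float) / scale
    return x / (1.0 + x)


def unit_to_exchange(t: np.ndarray, scale: float = 1000.0) -> np.ndarray:
    """Inverse of :func:`exchange_to_unit`."""
    t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0 - 1e-12)
    return scale * t / (1.0 - t)


def directed_fluxes(expanded: NetworkModel, state: FluxState) -> tuple[list[tuple[Reaction, float]], dict[str, float]]:
    """Forward/backward flux of every variant reaction of an expanded model.

    Returns the list of (directed reaction, flux) where backward directions
    appear as reactions with educts/products swapped, plus the total
    consumption of every pool (used as the EMU balance diagonal).
    """
    parent_idx = state.model.reaction_index
    directed: list[tuple[Reaction, float]] = []
    consumption: dict[str, float] = {}
    fwd_all = state.forward
    bwd_all = state.backward
    for r in expanded.reactions:
        pid = r.parent or r.id
        j = parent_idx[pid]
        w = r.variant_weight
        fwd = fwd_all[j] * w
        bwd = bwd_all[j] * w if r.bidirectional else 0.0
        if fwd > 0:
            directed.append((r, fwd))
            for met, _ in r.educts:
                consumption[met] = consumption.get(met, 0.0) + fwd
        if bwd > 0:
            rev = replace(r, educts=r.products, products=r.educts)
            directed.append((rev, bwd))
            for met, _ in rev.educts:
                consumption[met] = consumption.get(met, 0.0) + bwd
    return directed, consumption
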