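"""Elementary metabolite unit (EMU) decomposition and MID simulation.

An EMU is a subset of a metabolite's carbon atoms. At isotopic steady state
the mass isotopomer distribution (MID) of every EMU of size ``s`` satisfies
a linear balance given the MIDs of all

* EMUs of smaller size (entering through cleavage/condensation reactions,
  combined by convolution), and
* input-pool EMUs (tracer substrates), whose MIDs are known.

Decomposing the network into the minimal EMU closure of a set of target
fragments therefore yields a cascade of small linear systems, solved level
by level in order of EMU size. This reproduces the full nonlinear
positional-isotopomer balance exactly, at a tiny fraction of its dimension;
:func:`isotopomer_oracle` provides that full brute-force balance for
verification on small networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from chemoflux.network import (
    FluxState,
    NetworkModel,
    NetworkError,
    Reaction,
    expand_scrambling,
)


class EMU(NamedTuple):
    met: str
    atoms: tuple[int, ...]  # 1-based carbon positions, sorted

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:  # e.g. "MAL{1,2,4}"
        return f"{self.met}{{{','.join(map(str, self.atoms))}}}"


def emu(met: str, atoms) -> EMU:
    return EMU(met, tuple(sorted(int(a) for a in atoms)))


def full_emu(model: NetworkModel, met: str) -> EMU:
    return emu(met, range(1, model.metabolites[met].n_carbons + 1))


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class _Term:
    """One inflow term of an EMU balance: directed flux x product of parts."""

    row: int
    dirflux: int
    parts: tuple[EMU, ...]  # known parts (smaller or input EMUs)


@dataclass
class _Level:
    size: int
    emus: list[EMU]
    index: dict[EMU, int]
    # same-size couplings: (row, col, dirflux index)
    couplings: list[tuple[int, int, int]] = field(default_factory=list)
    terms: list[_Term] = field(default_factory=list)


@dataclass
class EMUSystem:
    """Level-ordered EMU balance cascade for one network."""

    model: NetworkModel            # parent model (fluxes live here)
    expanded: NetworkModel         # scrambling-expanded variant model
    targets: list[EMU]
    levels: list[_Level]
    input_emus: list[EMU]
    # directed reactions: (variant reaction, parent index, direction)
    directed: list[tuple[Reaction, int, int]]
    consumption: dict[str, list[tuple[int, int]]]  # pool -> [(dirflux, count)]
    _compiled: list | None = None

    @property
    def n_emus(self) -> int:
        return sum(len(lv.emus) for lv in self.levels)

    def dirflux_values(self, flux: FluxState) -> np.ndarray:
        if not self.directed:
            return np.zeros(0)
        fwd = flux.forward
        bwd = flux.backward
        pidx = np.array([p for _, p, _ in self.directed])
        sign = np.array([s for _, _, s in self.directed])
        w = np.array([r.variant_weight for r, _, _ in self.directed])
        return np.where(sign > 0, fwd[pidx], bwd[pidx]) * w

    def compiled(self) -> list:
        """Index-array form of the cascade for fast repeated assembly."""
        if self._compiled is None:
            self._compiled = []
            for lv in self.levels:
                diag_rows, diag_ks, diag_cs = [], [], []
                for row, e in enumerate(lv.emus):
                    for k, c in self.consumption.get(e.met, []):
                        diag_rows.append(row)
                        diag_ks.append(k)
                        diag_cs.append(c)
                coup = np.array(
                    [(r, c, k) for r, c, k in lv.couplings], dtype=int
                ).reshape(-1, 3)
                groups: dict[tuple, list[tuple[int, int]]] = {}
                for t in lv.terms:
                    groups.setdefault(t.parts, []).append((t.row, t.dirflux))
                term_groups = [
                    (parts, np.array([r for r, _ in lst]), np.array([k for _, k in lst]))
                    for parts, lst in groups.items()
                ]
                self._compiled.append(
                    {
                        "size": lv.size,
                        "emus": lv.emus,
                        "diag": (
                            np.array(diag_rows, int),
                            np.array(diag_ks, int),
                            np.array(diag_cs, float),
                        ),
                        "coup": coup,
                        "terms": term_groups,
                    }
                )
        return self._compiled


def _directed_structure(model: NetworkModel, expanded: NetworkModel):
    """Enumerate directed variant reactions and per-pool consumption terms."""
    parent_idx = model.reaction_index
    directed: list[tuple[Reaction, int, int]] = []
    consumption: dict[str, list[tuple[int, int]]] = {}
    for rxn in expanded.reactions:
        pid = rxn.parent or rxn.id
        j = parent_idx[pid]
        dirs = [(rxn, +1)]
        if rxn.bidirectional:
            dirs.append((replace(rxn, educts=rxn.products, products=rxn.educts), -1))
        for drxn, sign in dirs:
            k = len(directed)
            directed.append((drxn, j, sign))
            counts: dict[str, int] = {}
            for met, _ in drxn.educts:
                counts[met] = counts.get(met, 0) + 1
            for met, c in counts.items():
                consumption.setdefault(met, []).append((k, c))
    return directed, consumption


def decompose(model: NetworkModel, targets: list[EMU]) -> EMUSystem:
    """Build the minimal EMU closure for the given target EMUs.

    ``model`` is the parent network; scrambling variants are generated
    internally. Raises if a target references an unknown metabolite or is
    unreachable from any input pool.
    """
    for t in targets:
        if t.met not in model.metabolites:
            raise NetworkError(f"target EMU on undeclared metabolite {t.met}")
        n = model.metabolites[t.met].n_carbons
        if not t.atoms or t.atoms[-1] > n:
            raise NetworkError(f"target {t} exceeds {t.met}'s {n} carbons")
    expanded = expand_scrambling(model)
    directed, consumption = _directed_structure(model, expanded)

    # map: balanced pool -> [(dirflux index, product occurrence letters, educts)]
    producers: dict[str, list[tuple[int, str, tuple]]] = {}
    for k, (drxn, _, _) in enumerate(directed):
        for met, letters in drxn.products:
            if letters and model.metabolites[met].role == "balanced":
                producers.setdefault(met, []).append((k, letters, drxn.educts))

    balance_emus: dict[EMU, list[tuple[int, tuple[EMU, ...]]]] = {}
    input_emus: set[EMU] = set()
    stack = [emu(t.met, t.atoms) for t in targets]
    while stack:
        e = stack.pop()
        if model.metabolites[e.met].role != "balanced":
            input_emus.add(e)
            continue
        if e in balance_emus:
            continue
        if e.met not in producers:
            raise NetworkError(
                f"metabolite {e.met} is never produced; {e} unreachable from inputs"
            )
        terms = []
        for k, letters, educts in producers[e.met]:
            wanted = {letters[a - 1] for a in e.atoms}
            parts = []
            for emet, eletters in educts:
                pos = tuple(
                    i + 1 for i, ch in enumerate(eletters) if ch in wanted
                )
                if pos:
                    parts.append(emu(emet, pos))
            if sum(p.size for p in parts) != e.size:
                raise NetworkError(
                    f"atom bookkeeping failure for {e} in directed reaction {k}"
                )
            parts = tuple(sorted(parts))
            terms.append((k, parts))
            for p in parts:
                if model.metabolites[p.met].role != "balanced":
                    input_emus.add(p)
                elif p not in balance_emus:
                    stack.append(p)
        balance_emus[e] = terms

    sizes = sorted({e.size for e in balance_emus})
    levels = []
    for s in sizes:
        emus_s = sorted(e for e in balance_emus if e.size == s)
        lv = _Level(size=s, emus=emus_s, index={e: i for i, e in enumerate(emus_s)})
        for e in emus_s:
            row = lv.index[e]
            for k, parts in balance_emus[e]:
                if (
                    len(parts) == 1
                    and parts[0].size == s
                    and model.metabolites[parts[0].met].role == "balanced"
                ):
                    lv.couplings.append((row, lv.index[parts[0]], k))
                else:
                    lv.terms.append(_Term(row=row, dirflux=k, parts=parts))
        levels.append(lv)

    return EMUSystem(
        model=model,
        expanded=expanded,
        targets=list(targets),
        levels=levels,
        input_emus=sorted(input_emus),
        directed=directed,
        consumption=consumption,
    )


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cauchy product of two MIDs; the MID of the union of two EMUs."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


def simulate_mids(
    system: EMUSystem,
    flux: FluxState,
    tracer_input: dict[EMU, np.ndarray],
) -> dict[EMU, np.ndarray]:
    """Solve the EMU cascade for one flux state and tracer input.

    ``tracer_input`` must provide a MID for every EMU in
    ``system.input_emus``. Returns MIDs for every balanced EMU of the
    closure (targets included). Raises :class:`SimulationError` naming the
    pool if a level matrix is singular (pool without influx).
    """
    for e in system.input_emus:
        if e not in tracer_input:
            raise SimulationError(f"missing tracer input MID for {e}")
    vals = system.dirflux_values(flux)
    scale = max(float(np.max(vals)), 1.0) if vals.size else 1.0
    solved: dict[EMU, np.ndarray] = dict(tracer_input)
    for lv in system.compiled():
        emus = lv["emus"]
        n = len(emus)
        A = np.zeros((n, n))
        rhs = np.zeros((n, lv["size"] + 1))
        diag_rows, diag_ks, diag_cs = lv["diag"]
        np.subtract.at(np.reshape(A, -1), diag_rows * (n + 1), vals[diag_ks] * diag_cs)
        coup = lv["coup"]
        if coup.size:
            np.add.at(A, (coup[:, 0], coup[:, 1]), vals[coup[:, 2]])
        for parts, rows, ks in lv["terms"]:
            y = solved[parts[0]]
            for p in parts[1:]:
                y = np.convolve(y, solved[p])
            np.add.at(rhs, rows, -np.outer(vals[ks], y))
        try:
            X = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            diag = np.abs(np.diag(A))
            bad = emus[int(np.argmin(diag))]
            raise SimulationError(
                f"singular EMU system at size {lv['size']}: pool {bad.met} has no influx"
            ) from None
        if not np.all(np.isfinite(X)) or np.max(np.abs(A @ X - rhs)) > 1e-6 * scale:
            raise SimulationError(f"ill-conditioned EMU system at size {lv['size']}")
        sums = X.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = emus[int(np.argmax(np.abs(sums - 1.0)))]
            raise SimulationError(f"MID of {bad} does not normalize (sum={sums.max()})")
        X /= sums[:, None]
        for row, e in enumerate(emus):
            solved[e] = X[row]
    return {e: solved[e] for lv in system.levels for e in lv.emus}


# ---------------------------------------------------------------------------
# brute-force positional isotopomer oracle
# ---------------------------------------------------------------------------

_MAX_PATTERNS = 1 << 21


def _marginal(x: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    """Marginal joint distribution of a subset of carbon positions."""
    n = x.ndim
    keep = [p - 1 for p in positions]
    other = tuple(i for i in range(n) if i not in keep)
    m = x.sum(axis=other) if other else x
    # axes of m follow sorted(keep); reorder to `positions` order
    order = np.argsort(np.argsort(keep))
    return np.moveaxis(m, range(len(keep)), order)


def isotopomer_oracle(
    model: NetworkModel,
    flux: FluxState,
    tracer_input: dict[str, np.ndarray],
    tol: float = 1e-13,
    max_iter: int = 200000,
) -> dict[str, np.ndarray]:
    """Steady state of the full positional-isotopomer balance, as MIDs.

    ``tracer_input`` maps every input pool to its positional isotopomer
    tensor of shape (2,)*n (axis i = carbon i, index 1 = 13C). Only
    feasible for small networks; raises if the pattern space exceeds
    ~2 million states. Solved by damped fixed-point iteration of

        x_pool = (sum of inflow pattern distributions) / total consumption

    which converges for any feasible flux state, then verified against the
    balance residual.
    """
    expanded = expand_scrambling(model)
    directed, consumption = _directed_structure(model, expanded)
    vals_list = EMUSystem(
        model=model,
        expanded=expanded,
        targets=[],
        levels=[],
        input_emus=[],
        directed=directed,
        consumption=consumption,
    ).dirflux_values(flux)

    pools = [m for m in model.metabolites.values() if m.role == "balanced"]
    if sum(2 ** p.n_carbons for p in pools) > _MAX_PATTERNS:
        raise NetworkError("network too large for isotopomer enumeration")
    for p in pools:
        if p.id not in consumption or not any(
            vals_list[k] > 0 for k, _ in consumption[p.id]
        ):
            raise SimulationError(f"pool {p.id} has no outflux")

    x: dict[str, np.ndarray] = {}
    for p in pools:
        t = np.zeros((2,) * p.n_carbons)
        t[(0,) * p.n_carbons] = 1.0
        x[p.id] = t
    for met, dist in tracer_input.items():
        x[met] = np.asarray(dist, float)

    cons_total = {
        p.id: sum(vals_list[k] * c for k, c in consumption.get(p.id, []))
        for p in pools
    }

    # precompute production structure per pool
    prod: dict[str, list[tuple[float, str, tuple]]] = {p.id: [] for p in pools}
    for k, (drxn, _, _) in enumerate(directed):
        v = vals_list[k]
        if v <= 0:
            continue
        for met, letters in drxn.products:
            if letters and met in prod:
                prod[met].append((v, letters, drxn.educts))

    balanced_ids = [p.id for p in pools]

    def pool_inflow(pid: str) -> np.ndarray:
        inflow = np.zeros_like(x[pid])
        for v, letters, educts in prod[pid]:
            # joint distribution over the product's carbons
            tensors = []
            axes_letters = []
            for emet, eletters in educts:
                pos = tuple(
                    i + 1 for i, ch in enumerate(eletters) if ch in letters
                )
                if not pos:
                    continue
                tensors.append(_marginal(x[emet], pos))
                axes_letters.extend(eletters[i - 1] for i in pos)
            joint = tensors[0]
            for t in tensors[1:]:
                joint = np.multiply.outer(joint, t)
            # reorder axes to product carbon order
            order = [axes_letters.index(ch) for ch in letters]
            inflow += v * joint.transpose(order)
        return inflow

    for it in range(max_iter):
        delta = 0.0
        for pid in balanced_ids:
            new = pool_inflow(pid) / cons_total[pid]
            # keep each pool on the probability simplex: condensation
            # cycles otherwise admit spurious sub-stochastic fixed points
            total = new.sum()
            if total > 0:
                new = new / total
            delta = max(delta, float(np.max(np.abs(new - x[pid]))))
            x[pid] = new
        if delta < tol:
            break
    else:
        raise SimulationError("isotopomer fixed point did not converge")
    # verify the unnormalized balances actually hold at the solution
    scale = max(cons_total.values())
    for pid in balanced_ids:
        resid = np.max(np.abs(cons_total[pid] * x[pid] - pool_inflow(pid)))
        if resid > 1e-8 * scale:
            raise SimulationError(
                f"isotopomer balance residual {resid:.2e} at pool {pid}"
            )

    out: dict[str, np.ndarray] = {}
    for pid in balanced_ids:
        n = x[pid].ndim
        mid = np.zeros(n + 1)
        for pattern in itertools.product((0, 1), repeat=n):
            mid[sum(pattern)] += x[pid][pattern]
        out[pid] = mid
    return out


def mids_to_frame(mids: dict[EMU, np.ndarray]):
    """Simulated MIDs as a tidy DataFrame (metabolite, fragment, m0..mn)."""
    import pandas as pd

    rows = []
    for e, mid in sorted(mids.items()):
        for k, v in enumerate(mid):
            rows.append(
                {
                    "metabolite": e.met,
                    "fragment": ",".join(map(str, e.atoms)),
                    "mass_shift": k,
                    "fraction": v,
                }
            )
    return pd.DataFrame(rows)
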