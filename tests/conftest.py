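"""Shared fixtures: bundled model, toy networks, helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from chemoflux.network import (
    FluxState,
    build_flux_basis,
    load_bundled,
    load_network,
)

# ---------------------------------------------------------------------------
# toy network documents
# ---------------------------------------------------------------------------

LINEAR_CHAIN = """
name: linear2
metabolites:
  - {id: Ain, carbons: 2, role: input}
  - {id: A, carbons: 2}
  - {id: B, carbons: 2}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Ain#ab -> A#ab"}
  - {id: ab, equation: "A#ab -> B#ab"}
  - {id: out, equation: "B#ab -> Out"}
"""

# split network where one route cleaves and recombines: with a uniformly
# labeled tracer component, intact (bimodal) and recombined (convolved)
# molecules are distinguishable, so the split is identifiable from
# full-backbone MIDs. Three free nets (uptake, split, shunt) + one exchange.
BRANCH = """
name: branch
metabolites:
  - {id: Sin, carbons: 3, role: input}
  - {id: S, carbons: 3}
  - {id: A, carbons: 3}
  - {id: P, carbons: 2}
  - {id: Q, carbons: 1}
  - {id: B, carbons: 3}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Sin#abc -> S#abc"}
  - {id: p1, equation: "S#abc -> A#abc"}
  - {id: p2, equation: "S#abc -> P#ab + Q#c"}
  - {id: rec, equation: "P#ab + Q#c -> B#abc"}
  - {id: iso, equation: "A#abc -> B#abc", bidirectional: true}
  - {id: outa, equation: "A#abc -> Out"}
  - {id: outb, equation: "B#abc -> Out"}
"""

# p3 duplicates p1's atom map: the p1/p3 split is structurally undetermined
BRANCH_NONIDENT = """
name: branch_nonident
metabolites:
  - {id: Sin, carbons: 3, role: input}
  - {id: S, carbons: 3}
  - {id: A, carbons: 3}
  - {id: P, carbons: 2}
  - {id: Q, carbons: 1}
  - {id: B, carbons: 3}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Sin#abc -> S#abc"}
  - {id: p1, equation: "S#abc -> A#abc"}
  - {id: p3, equation: "S#abc -> A#abc"}
  - {id: p2, equation: "S#abc -> P#ab + Q#c"}
  - {id: rec, equation: "P#ab + Q#c -> B#abc"}
  - {id: iso, equation: "A#abc -> B#abc", bidirectional: true}
  - {id: outa, equation: "A#abc -> Out"}
  - {id: outb, equation: "B#abc -> Out"}
"""

# cleavage + condensation + symmetric pool + bidirectional loop; the hardest
# small topology: exercises convolution, scrambling and exchange
CYCLE = """
name: cycle
metabolites:
  - {id: Ain, carbons: 3, role: input}
  - {id: A, carbons: 3}
  - {id: B, carbons: 2}
  - {id: C, carbons: 1}
  - {id: D, carbons: 3}
  - {id: E, carbons: 4, symmetric: true}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Ain#abc -> A#abc"}
  - {id: cleave, equation: "A#abc -> B#bc + C#a"}
  - {id: iso, equation: "A#abc -> D#cba", bidirectional: true}
  - {id: cond, equation: "B#ab + B#cd -> E#adcb"}
  - {id: rej, equation: "E#abcd -> D#abc + C#d"}
  - {id: out_c, equation: "C#a -> Out"}
  - {id: out_d, equation: "D#abc -> Out"}
"""

# two-pool loop with a symmetric member, akin to a miniature TCA cycle
LOOP_SYM = """
name: loop_sym
metabolites:
  - {id: Xin, carbons: 2, role: input}
  - {id: P, carbons: 4}
  - {id: Q, carbons: 4, symmetric: true}
  - {id: R, carbons: 2}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Xin#ab -> R#ab"}
  - {id: cond, equation: "R#ab + R#cd -> P#abdc"}
  - {id: pq, equation: "P#abcd -> Q#abcd", bidirectional: true}
  - {id: split, equation: "Q#abcd -> R#ab + R#dc"}
  - {id: out_r, equation: "R#ab -> Out"}
"""

TOY_DOCS = {
    "linear2": LINEAR_CHAIN,
    "branch": BRANCH,
    "cycle": CYCLE,
    "loop_sym": LOOP_SYM,
}


@pytest.fixture(scope="session")
def bundled_model():
    return load_bundled()


@pytest.fixture(scope="session")
def bundled_basis(bundled_model):
    return build_flux_basis(bundled_model)


@pytest.fixture(scope="session")
def paper_state(bundled_basis):
    from chemoflux.synth import paper_flux_state

    return paper_flux_state(bundled_basis)


@pytest.fixture
def branch_model():
    return load_network(BRANCH)


@pytest.fixture
def cycle_model():
    return load_network(CYCLE)


# ---------------------------------------------------------------------------
# helpers for randomized toy cases
# ---------------------------------------------------------------------------

def tensor_mid(tensor: np.ndarray, atoms: tuple[int, ...]) -> np.ndarray:
    """MID of an atom subset from a positional isotopomer tensor."""
    out = np.zeros(len(atoms) + 1)
    for pat in itertools.product((0, 1), repeat=tensor.ndim):
        out[sum(pat[a - 1] for a in atoms)] += tensor[pat]
    return out


def random_input_tensor(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random positional isotopomer distribution (mixture of 3 patterns)."""
    t = np.zeros((2,) * n)
    fracs = rng.dirichlet(np.ones(3))
    for f in fracs:
        pat = tuple(rng.integers(0, 2, n))
        t[pat] += f
    return t


def random_flux_state(model, rng: np.random.Generator, max_tries: int = 300) -> FluxState:
    """Random feasible flux state on a toy network (all free nets positive)."""
    basis = build_flux_basis(model)
    uni = np.array([not r.bidirectional for r in model.reactions])
    for _ in range(max_tries):
        free = rng.uniform(0.5, 8.0, len(basis.free_net))
        exch = rng.uniform(0.0, 5.0, len(basis.free_exchange))
        st = basis.realize(free, exch)
        if np.all(st.net[uni] >= 0) and np.all(np.abs(st.net) <= 50):
            return st
    raise RuntimeError(f"no feasible random flux state for {model.name}")
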