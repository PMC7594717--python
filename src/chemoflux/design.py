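"""A priori tracer experiment design for flux identifiability.

Before a labeling experiment, candidate glucose tracer mixtures are scored
by the Fisher information they carry about the free fluxes: with
measurement sensitivities S = d(simulated measurements)/d(parameters) and
measurement covariance Sigma, J = S' Sigma^-1 S. Mixtures are ranked by
D-optimality on the identifiable subspace (pseudo-log-determinant of J);
A-optimality (trace of the pseudo-inverse) is available as an alternative.
The mixture search scans the simplex over the candidate set on a
deterministic grid with a lexicographic tie-break.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chemoflux.fitting import FluxFitProblem
from chemoflux.mids import TracerMixture


@dataclass(frozen=True)
class TracerCandidate:
    name: str
    pattern: tuple[int, ...]
    cost_weight: float = 1.0


#: the candidate set considered for the labeling experiment
CANDIDATE_TRACERS = (
    TracerCandidate("U-12C", (0, 0, 0, 0, 0, 0)),
    TracerCandidate("U-13C", (1, 1, 1, 1, 1, 1)),
    TracerCandidate("1-13C", (1, 0, 0, 0, 0, 0)),
    TracerCandidate("1,2-13C", (1, 1, 0, 0, 0, 0)),
    TracerCandidate("6-13C", (0, 0, 0, 0, 0, 1)),
    TracerCandidate("5,6-13C", (0, 0, 0, 0, 1, 1)),
)

#: the mixture chosen for the labeling experiment (named preset)
CHOSEN_MIXTURE = {"U-13C": 0.67, "1-13C": 0.33}


@dataclass
class DesignResult:
    fractions: dict[str, float]
    information: np.ndarray
    score: float
    criterion: str
    predicted_sds: dict[str, float] = field(default_factory=dict)


def simulated_measurement_vector(problem: FluxFitProblem, theta: np.ndarray) -> np.ndarray:
    """Stacked simulated measurements (MIDs then rates) at a parameter vector."""
    state = problem.realize(theta)
    sim_mids, sim_rates = problem.simulate_measurements(state)
    return np.concatenate([np.concatenate(sim_mids), sim_rates]) if sim_mids else sim_rates


def _sigma_inv_diag(problem: FluxFitProblem) -> np.ndarray:
    sds = [m.sd for m in problem.dataset.mids] + [
        np.array([r.sd]) for r in problem.dataset.rates
    ]
    return 1.0 / np.concatenate(sds) ** 2


def fisher_information(
    problem: FluxFitProblem,
    theta: np.ndarray,
    rel_step: float = 1e-5,
) -> np.ndarray:
    """J = S' Sigma^-1 S by central finite differences of the simulated
    measurement vector with respect to the free parameters."""
    theta = np.asarray(theta, float)
    w = _sigma_inv_diag(problem)
    lo, hi = problem.bounds()
    n = theta.size
    cols = []
    for j in range(n):
        h = rel_step * max(abs(theta[j]), 1e-3 * (hi[j] - lo[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        cols.append(
            (
                simulated_measurement_vector(problem, tp)
                - simulated_measurement_vector(problem, tm)
            )
            / (2 * h)
        )
    S = np.column_stack(cols)
    J = S.T @ (w[:, None] * S)
    return 0.5 * (J + J.T)


_RANK_TOL = 1e-9


def design_score(J: np.ndarray, criterion: str = "D") -> float:
    """Scalar design criterion of an information matrix.

    D: pseudo-log-determinant (sum of log of nonzero eigenvalues of the
    identifiable block). A: trace of the pseudo-inverse (smaller is
    better; returned negated so larger is always better).
    """
    ev = np.linalg.eigvalsh(np.asarray(J, float))
    ev = ev[ev > _RANK_TOL * max(ev.max(), 1.0)]
    if criterion == "D":
        return float(np.sum(np.log(ev))) if ev.size else -np.inf
    if criterion == "A":
        return -float(np.sum(1.0 / ev)) if ev.size else -np.inf
    raise ValueError(f"unknown criterion {criterion!r}")


def mixture_from_fractions(
    candidates: list[TracerCandidate], fractions: list[float]
) -> TracerMixture:
    return TracerMixture(
        tuple(
            (c.pattern, f) for c, f in zip(candidates, fractions) if f > 0
        )
    )


def _simplex_grid(n: int, steps: int):
    """All compositions of `steps` grid units over n components."""
    for cuts in itertools.combinations(range(steps + n - 1), n - 1):
        parts = []
        prev = -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(steps + n - 2 - prev)
        yield tuple(p / steps for p in parts)


def optimize_mixture(
    make_problem,
    theta: np.ndarray,
    candidates: list[TracerCandidate] = list(CANDIDATE_TRACERS),
    criterion: str = "D",
    grid_step: float = 0.1,
    max_active: int = 3,
) -> DesignResult:
    """Deterministic simplex-grid search for the best tracer mixture.

    ``make_problem(mixture)`` must return a :class:`FluxFitProblem` whose
    dataset uses that tracer mixture (measured values are irrelevant; only
    the measurement configuration and SDs matter). All subsets of at most
    ``max_active`` candidates are scanned on a grid of the given step; ties
    break lexicographically on the fraction vector, so results are
    reproducible.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    steps = round(1.0 / grid_step)
    best = None
    for subset in itertools.combinations(range(len(candidates)), min(max_active, len(candidates))):
        for fracs in _simplex_grid(len(subset), steps):
            full = [0.0] * len(candidates)
            for i, f in zip(subset, fracs):
                full[i] = f
            key = tuple(full)
            if best is not None and best[2] == key:
                continue
            mixture = mixture_from_fractions(candidates, full)
            problem = make_problem(mixture)
            J = fisher_information(problem, theta)
            score = design_score(J, criterion)
            if best is None or score > best[0] + 1e-12 or (
                abs(score - best[0]) <= 1e-12 and key < best[2]
            ):
                best = (score, J, key, problem)
    score, J, key, problem = best
    ev, V = np.linalg.eigh(J)
    mask = ev > _RANK_TOL * max(ev.max(), 1.0)
    pinv = (V[:, mask] / ev[mask]) @ V[:, mask].T
    names = problem.basis.free_net + [f"x_{r}" for r in problem.basis.free_exchange]
    sds = {n: float(np.sqrt(max(pinv[i, i], 0.0))) for i, n in enumerate(names)}
    return DesignResult(
        fractions={c.name: f for c, f in zip(candidates, key) if f > 0},
        information=J,
        score=score,
        criterion=criterion,
        predicted_sds=sds,
    )


def rank_mixtures(
    make_problem,
    theta: np.ndarray,
    mixtures: dict[str, TracerMixture],
    criterion: str = "D",
) -> pd.DataFrame:
    """Score a set of named mixtures; higher score = more informative."""
    rows = []
    for name, mixture in mixtures.items():
        problem = make_problem(mixture)
        J = fisher_information(problem, theta)
        rows.append({"mixture": name, "score": design_score(J, criterion)})
    return pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
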