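"""Weighted least-squares flux estimation with statistics.

Free fluxes (net branch-point fluxes plus bounded exchange-flux
transforms) are fitted by minimizing the variance-weighted sum of squared
residuals (SSR) between simulated and measured quantities: corrected MIDs
of the measurement panel and biomass-specific extracellular rates. Each
measurement group carries a multiplicative scale factor that is profiled
out analytically at every objective evaluation (variable projection), so
the optimizer sees only the flux parameters while the parameter count for
the chi-square acceptance test still includes the scale factors.

A multi-start heuristic combats local minima: random feasible starting
flux distributions (rate-informed for directly measured fluxes), a cheap
trust-region screen of every start, a tight polish of the best candidates,
and seeded perturbation restarts around the incumbent; an optional
gradient-free warm-up per start is available. Goodness of fit is judged
against the upper-alpha chi-square quantile at (measurements - parameters)
degrees of freedom; simultaneous confidence intervals come from profiling
the SSR or from local curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from chemoflux.emu import decompose, emu, simulate_mids
from chemoflux.mids import (
    MIDMeasurement,
    PAPER_MIXTURE,
    TracerMixture,
    fit_group_scale,
    tracer_input_mids,
)
from chemoflux.network import (
    FluxBasis,
    FluxState,
    NetworkModel,
    build_flux_basis,
    unit_to_exchange,
    exchange_to_unit,
)


@dataclass(frozen=True)
class RateMeasurement:
    """An extracellular rate: 'mu' or a reaction id, value, standard deviation."""

    name: str
    value: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"rate {self.name}: non-positive SD")


@dataclass
class FitDataset:
    mids: list[MIDMeasurement]
    rates: list[RateMeasurement]
    mixture: TracerMixture = PAPER_MIXTURE

    @property
    def n_measurements(self) -> int:
        return sum(len(m.mid) for m in self.mids) + len(self.rates)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for m in self.mids:
            if m.group not in seen:
                seen.append(m.group)
        return seen


# default physiological boxes for random starts / bounds, micromol/gCDW/h
DEFAULT_NET_BOUNDS = {
    "pts": (500.0, 10000.0),
    "pca_upt": (0.0, 200.0),
    "__mu__": (0.05, 0.8),
    "zwf": (0.0, 6000.0),
    "pyc": (0.0, 5000.0),
    "pck": (0.0, 3000.0),
    "mez": (0.0, 3000.0),
}


@dataclass
class FitConfig:
    net_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    exchange_scale: float = 1000.0
    exchange_t_max: float = 0.95
    natural_abundance_inputs: bool = False
    penalty_weight: float = 1e3
    stage1_maxfev: int = 0       # optional gradient-free warm-up per start
    screen_max_nfev: int = 80    # cheap trust-region screen per start
    polish_max_nfev: int = 800   # tight refinement of the best starts
    n_polish: int = 3
    n_kicks: int = 16            # perturbation restarts around the incumbent
    xtol: float = 3e-16
    ftol: float = 1e-15
    alpha: float = 0.05


class FluxFitProblem:
    """Binds a network, a free-flux basis and a dataset into an objective."""

    def __init__(
        self,
        model: NetworkModel,
        dataset: FitDataset,
        basis: FluxBasis | None = None,
        config: FitConfig | None = None,
        pool_map: dict[str, str] | None = None,
    ):
        self.model = model
        self.dataset = dataset
        self.basis = basis if basis is not None else build_flux_basis(model)
        self.config = config or FitConfig()
        self.pool_map = pool_map or {}
        pools = []
        for m in dataset.mids:
            pool = m.fragment.pool or m.fragment.metabolite
            pool = self.pool_map.get(pool, pool)
            if pool not in model.metabolites:
                raise KeyError(f"measured pool {pool} not in model")
            pools.append(pool)
        self._pools = pools
        targets = sorted(
            {emu(p, range(1, model.metabolites[p].n_carbons + 1)) for p in pools}
        )
        self.system = decompose(model, targets)
        self.tracer = tracer_input_mids(
            self.system,
            dataset.mixture,
            natural_abundance=self.config.natural_abundance_inputs,
        )
        self._uni = np.array([not r.bidirectional for r in model.reactions])
        self._rate_idx = {
            r.id: i for i, r in enumerate(model.reactions)
        }
        # chi-square bookkeeping: free fluxes + one scale factor per group
        self.n_params = self.basis.n_free + len(dataset.groups)
        self.n_meas = dataset.n_measurements

    # -- parameter vector ------------------------------------------------
    @property
    def n_theta(self) -> int:
        return len(self.basis.free_net) + len(self.basis.free_exchange)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        merged = {**DEFAULT_NET_BOUNDS, **self.config.net_bounds}
        for name in self.basis.free_net:
            l, h = merged.get(name, (-5000.0, 5000.0))
            lo.append(l)
            hi.append(h)
        for _ in self.basis.free_exchange:
            lo.append(0.0)
            hi.append(self.config.exchange_t_max)
        return np.array(lo), np.array(hi)

    def realize(self, theta: np.ndarray) -> FluxState:
        k = len(self.basis.free_net)
        nets = np.asarray(theta[:k], float)
        ts = np.asarray(theta[k:], float)
        exch = unit_to_exchange(ts, self.config.exchange_scale)
        return self.basis.realize(nets, exch)

    def theta_from_state(self, state: FluxState) -> np.ndarray:
        nets = self.basis.extract_free(state)
        exch = self.basis.extract_exchange(state)
        return np.concatenate(
            [nets, exchange_to_unit(exch, self.config.exchange_scale)]
        )

    # -- simulation -------------------------------------------------------
    def simulate_measurements(self, state: FluxState):
        """Simulated MID per measurement and simulated rate per rate row."""
        mids = simulate_mids(self.system, state, self.tracer)
        sim_mids = []
        for m, pool in zip(self.dataset.mids, self._pools):
            e = emu(pool, range(1, self.model.metabolites[pool].n_carbons + 1))
            sim_mids.append(mids[e])
        sim_rates = np.array(
            [
                state.mu if r.name == "mu" else state.net[self._rate_idx[r.name]]
                for r in self.dataset.rates
            ]
        )
        return sim_mids, sim_rates

    def group_scales(self, sim_mids) -> dict[str, float]:
        scales = {}
        for g in self.dataset.groups:
            s, m, v = [], [], []
            for meas, sim in zip(self.dataset.mids, sim_mids):
                if meas.group == g:
                    s.append(sim)
                    m.append(meas.mid)
                    v.append(meas.sd)
            scales[g] = fit_group_scale(
                np.concatenate(s), np.concatenate(m), np.concatenate(v)
            )
        return scales

    def _penalties(self, state: FluxState) -> np.ndarray:
        viol = np.maximum(0.0, -state.net[self._uni])
        scale = max(float(np.max(np.abs(state.net))), 1.0)
        return self.config.penalty_weight * viol / scale

    def residuals(self, theta: np.ndarray, with_penalty: bool = True) -> np.ndarray:
        state = self.realize(theta)
        pen = self._penalties(state)
        n_res = self.n_meas
        try:
            sim_mids, sim_rates = self.simulate_measurements(state)
        except Exception:
            out = np.full(n_res, 1e3)
            return np.concatenate([out, pen + 1.0]) if with_penalty else out
        scales = self.group_scales(sim_mids)
        res = []
        for meas, sim in zip(self.dataset.mids, sim_mids):
            w = scales[meas.group]
            res.append((w * sim - meas.mid) / meas.sd)
        for r, s in zip(self.dataset.rates, sim_rates):
            res.append(np.array([(s - r.value) / r.sd]))
        res = np.concatenate(res)
        return np.concatenate([res, pen]) if with_penalty else res

    def ssr(self, theta: np.ndarray) -> float:
        return float(np.sum(self.residuals(theta, with_penalty=False) ** 2))

    def ssr_with_penalty(self, theta: np.ndarray) -> float:
        return float(np.sum(self.residuals(theta) ** 2))

    # -- random starts -----------------------------------------------------
    def sample_start(
        self,
        rng: np.random.Generator,
        max_tries: int = 500,
        rate_informed: bool = True,
    ) -> np.ndarray:
        """Random feasible start.

        Free net fluxes are drawn uniformly in their physiological boxes;
        free fluxes that are directly measured as extracellular rates
        (uptakes, growth rate) are instead drawn around their measured
        values (3 SD), which concentrates starts in the data-supported
        scale without using any unmeasured information. Starts violating a
        unidirectional flux direction are rejected and redrawn.
        """
        lo, hi = self.bounds()
        k = len(self.basis.free_net)
        measured = {r.name: r for r in self.dataset.rates}
        for _ in range(max_tries):
            theta = rng.uniform(lo, hi)
            if rate_informed:
                for j, name in enumerate(self.basis.free_net):
                    key = "mu" if name == "__mu__" else name
                    if key in measured:
                        r = measured[key]
                        theta[j] = np.clip(
                            rng.normal(r.value, 3.0 * r.sd), lo[j], hi[j]
                        )
            theta[k:] = rng.uniform(0.0, 0.9, size=self.n_theta - k)
            state = self.realize(theta)
            if np.all(state.net[self._uni] >= 0):
                return theta
        raise RuntimeError("could not sample a feasible starting flux distribution")


def weighted_ssr(free_params: np.ndarray, dataset: FitDataset, problem: FluxFitProblem) -> float:
    """Variance-weighted SSR at a free-parameter vector (spec operation)."""
    if dataset is not problem.dataset:
        raise ValueError("dataset does not match the problem context")
    return problem.ssr(np.asarray(free_params, float))


@dataclass
class FitResult:
    state: FluxState
    theta: np.ndarray
    ssr: float
    n_meas: int
    n_params: int
    chi2_threshold: float
    scales: dict[str, float]
    residuals: pd.DataFrame
    trace: list[tuple[int, float]]
    problem: FluxFitProblem

    @property
    def accepted(self) -> bool:
        return self.ssr <= self.chi2_threshold

    @property
    def dof(self) -> int:
        return self.n_meas - self.n_params

    def report(self) -> dict:
        return {
            "ssr": self.ssr,
            "n_measurements": self.n_meas,
            "n_parameters": self.n_params,
            "dof": self.dof,
            "chi2_threshold": self.chi2_threshold,
            "accepted": bool(self.accepted),
        }


def _residual_table(problem: FluxFitProblem, theta: np.ndarray) -> pd.DataFrame:
    state = problem.realize(theta)
    sim_mids, sim_rates = problem.simulate_measurements(state)
    scales = problem.group_scales(sim_mids)
    rows = []
    for meas, sim in zip(problem.dataset.mids, sim_mids):
        w = scales[meas.group]
        for k in range(len(meas.mid)):
            rows.append(
                {
                    "kind": "mid",
                    "name": f"{meas.fragment.metabolite} M+{k}",
                    "group": meas.group,
                    "measured": meas.mid[k],
                    "simulated": w * sim[k],
                    "sd": meas.sd[k],
                    "residual": (w * sim[k] - meas.mid[k]) / meas.sd[k],
                }
            )
    for r, s in zip(problem.dataset.rates, sim_rates):
        rows.append(
            {
                "kind": "rate",
                "name": r.name,
                "group": "",
                "measured": r.value,
                "simulated": s,
                "sd": r.sd,
                "residual": (s - r.value) / r.sd,
            }
        )
    return pd.DataFrame(rows)


def fit_fluxes(
    problem: FluxFitProblem,
    n_starts: int = 20,
    seed: int = 0,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Multi-start weighted least-squares flux fit.

    Every random feasible start is screened with a short trust-region run
    (optionally preceded by a gradient-free warm-up), the best few are
    polished tightly, and seeded perturbation restarts around the incumbent
    guard against shallow local minima. Deterministic for a given seed; the
    per-start SSR trace is retained (kick improvements appear with negative
    indices). ``theta0`` adds one user-supplied start.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = problem.bounds()
    cfg = problem.config
    xsc = _x_scale(problem)
    starts = []
    if theta0 is not None:
        starts.append(np.asarray(theta0, float))
    while len(starts) < n_starts + (1 if theta0 is not None else 0):
        starts.append(problem.sample_start(rng))

    screened: list[tuple[float, np.ndarray, int]] = []
    trace: list[tuple[int, float]] = []
    failures = []
    for i, th0 in enumerate(starts):
        try:
            th = np.clip(th0, lo, hi)
            if cfg.stage1_maxfev > 0:
                res1 = optimize.minimize(
                    problem.ssr_with_penalty,
                    th,
                    method="Powell",
                    bounds=list(zip(lo, hi)),
                    options={"maxfev": cfg.stage1_maxfev, "xtol": 1e-6},
                )
                th = np.clip(res1.x, lo, hi)
            res2 = optimize.least_squares(
                problem.residuals,
                th,
                bounds=(lo, hi),
                xtol=1e-10,
                ftol=1e-12,
                max_nfev=cfg.screen_max_nfev,
                x_scale=xsc,
                tr_solver="exact",
            )
            ssr = problem.ssr(res2.x)
            screened.append((ssr, res2.x, i))
            trace.append((i, ssr))
        except Exception as exc:  # pragma: no cover - diagnostic path
            failures.append((i, repr(exc)))
            continue
    if not screened:
        raise RuntimeError(f"all {len(starts)} starts failed: {failures[:3]}")
    screened.sort(key=lambda t: t[0])

    best = None
    for ssr0, x0, i in screened[: max(cfg.n_polish, 1)]:
        res3 = optimize.least_squares(
            problem.residuals,
            x0,
            bounds=(lo, hi),
            xtol=cfg.xtol,
            ftol=cfg.ftol,
            gtol=1e-15,
            max_nfev=cfg.polish_max_nfev,
            x_scale=xsc,
            tr_solver="exact",
            jac="3-point",
        )
        ssr = problem.ssr(res3.x)
        trace.append((i, ssr))
        if best is None or ssr < best[1]:
            best = (res3.x, ssr)

    # perturbation restarts around the incumbent: escape shallow local minima
    for kick in range(cfg.n_kicks):
        size = np.exp(rng.uniform(np.log(0.5), np.log(12.0)))
        mask = rng.random(problem.n_theta) < rng.uniform(0.3, 1.0)
        th = best[0] + rng.normal(0.0, 1.0, problem.n_theta) * xsc * size * mask
        th = np.clip(th, lo, hi)
        try:
            rk = optimize.least_squares(
                problem.residuals, th, bounds=(lo, hi),
                xtol=1e-10, ftol=1e-12, max_nfev=cfg.screen_max_nfev,
                x_scale=xsc, tr_solver="exact",
            )
            sk = problem.ssr(rk.x)
            if sk < best[1] - 1e-9:
                rk2 = optimize.least_squares(
                    problem.residuals, rk.x, bounds=(lo, hi),
                    xtol=cfg.xtol, ftol=cfg.ftol, gtol=1e-15,
                    max_nfev=cfg.polish_max_nfev,
                    x_scale=xsc, tr_solver="exact", jac="3-point",
                )
                sk2 = problem.ssr(rk2.x)
                trace.append((-1 - kick, sk2))
                if sk2 < best[1]:
                    best = (rk2.x, sk2)
        except Exception:  # pragma: no cover - keep incumbent on failure
            continue
    theta, ssr = best
    state = problem.realize(theta)
    sim_mids, _ = problem.simulate_measurements(state)
    threshold = chi2_acceptance(problem.n_meas, problem.n_params, cfg.alpha)
    return FitResult(
        state=state,
        theta=theta,
        ssr=ssr,
        n_meas=problem.n_meas,
        n_params=problem.n_params,
        chi2_threshold=threshold,
        scales=problem.group_scales(sim_mids),
        residuals=_residual_table(problem, theta),
        trace=trace,
        problem=problem,
    )


def _x_scale(problem: FluxFitProblem) -> np.ndarray:
    lo, hi = problem.bounds()
    k = len(problem.basis.free_net)
    return np.concatenate(
        [np.maximum((hi[:k] - lo[:k]) * 0.05, 1e-3), np.full(problem.n_theta - k, 0.05)]
    )


def chi2_acceptance(n_meas: int, n_params: int, alpha: float = 0.05) -> float:
    """Maximally acceptable SSR: upper-alpha chi-square quantile at
    dof = n_meas - n_params."""
    dof = n_meas - n_params
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    return float(stats.chi2.ppf(1.0 - alpha, dof))


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceInterval:
    name: str
    estimate: float
    lower: float
    upper: float
    non_identifiable: bool = False


def _jacobian(problem: FluxFitProblem, theta: np.ndarray, rel_step: float = 1e-6):
    r0 = problem.residuals(theta, with_penalty=False)
    J = np.zeros((r0.size, theta.size))
    lo, hi = problem.bounds()
    for j in range(theta.size):
        h = rel_step * max(abs(theta[j]), 1e-3 * (hi[j] - lo[j]))
        tp = theta.copy()
        tp[j] = min(theta[j] + h, hi[j])
        tm = theta.copy()
        tm[j] = max(theta[j] - h, lo[j])
        J[:, j] = (
            problem.residuals(tp, with_penalty=False)
            - problem.residuals(tm, with_penalty=False)
        ) / (tp[j] - tm[j])
    return r0, J


def confidence_intervals(
    fit: FitResult,
    alpha: float = 0.05,
    mode: str = "profile",
    params: list[str] | None = None,
    max_expand: int = 40,
) -> list[ConfidenceInterval]:
    """Simultaneous confidence intervals for the free net fluxes.

    ``profile`` walks each free net flux away from the optimum, re-fitting
    all other parameters, until the SSR exceeds best SSR plus the
    chi-square quantile at the full parameter count (simultaneous
    threshold). Hitting the physiological box before the threshold flags
    the flux as non-identifiable. ``linearized`` uses local curvature; if
    the curvature is singular the affected parameters fall back to profile.
    """
    problem = fit.problem
    names = list(problem.basis.free_net)
    wanted = params if params is not None else names
    thr = fit.ssr + float(stats.chi2.ppf(1.0 - alpha, fit.n_params))
    lo, hi = problem.bounds()
    theta = fit.theta

    if mode == "linearized":
        _, J = _jacobian(problem, theta)
        JtJ = J.T @ J
        out = []
        try:
            cov = np.linalg.inv(JtJ)
            half = np.sqrt(
                np.maximum(np.diag(cov), 0.0)
                * stats.chi2.ppf(1.0 - alpha, fit.n_params)
            )
            for name in wanted:
                i = names.index(name)
                out.append(
                    ConfidenceInterval(
                        name, theta[i], theta[i] - half[i], theta[i] + half[i]
                    )
                )
            return out
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn(
                "singular curvature; falling back to profile intervals",
                RuntimeWarning,
            )
            mode = "profile"

    if mode != "profile":
        raise ValueError(f"unknown interval mode {mode!r}")

    out = []
    for name in wanted:
        i = names.index(name)
        bnds = []
        flagged = False
        for direction in (-1.0, +1.0):
            step = max(abs(theta[i]) * 0.02, 1e-3 * (hi[i] - lo[i]))
            prev_val, prev_ssr = theta[i], fit.ssr
            bound_val = None
            for _ in range(max_expand):
                val = prev_val + direction * step
                box = lo[i] if direction < 0 else hi[i]
                clipped = max(val, box) if direction < 0 else min(val, box)
                ssr = _profile_point(problem, theta, i, clipped)
                if ssr > thr:
                    # linear interpolation between prev and current
                    f = (thr - prev_ssr) / max(ssr - prev_ssr, 1e-12)
                    bound_val = prev_val + f * (clipped - prev_val)
                    break
                prev_val, prev_ssr = clipped, ssr
                if clipped == box:
                    flagged = True
                    bound_val = box
                    break
                step *= 1.8
            if bound_val is None:
                flagged = True
                bound_val = lo[i] if direction < 0 else hi[i]
            bnds.append(bound_val)
        out.append(
            ConfidenceInterval(name, theta[i], bnds[0], bnds[1], flagged)
        )
    return out


def _profile_point(problem: FluxFitProblem, theta: np.ndarray, i: int, value: float) -> float:
    lo, hi = problem.bounds()
    free = [j for j in range(theta.size) if j != i]

    def local(th_free):
        full = theta.copy()
        full[i] = value
        full[free] = th_free
        return problem.residuals(full)

    xsc = _x_scale(problem)
    res = optimize.least_squares(
        local,
        theta[free],
        bounds=(lo[free], hi[free]),
        xtol=1e-8,
        ftol=1e-9,
        max_nfev=300,
        x_scale=xsc[free],
        tr_solver="exact",
    )
    full = theta.copy()
    full[i] = value
    full[free] = res.x
    return problem.ssr(full)


# ---------------------------------------------------------------------------
# flux map normalization and cofactor/carbon accounting
# ---------------------------------------------------------------------------

def normalize_state(state: FluxState, reference: str = "pts", sds: dict[str, float] | None = None) -> pd.DataFrame:
    """Net fluxes as percent of a reference flux (glucose uptake by default).

    Signs of reverse net fluxes are preserved; absolute flux SDs, when
    supplied, are scaled by the same factor.
    """
    ref = state.net_of(reference)
    if ref == 0:
        raise ValueError(f"reference flux {reference} is zero")
    rows = []
    for i, r in enumerate(state.model.reactions):
        rows.append(
            {
                "reaction": r.id,
                "net": state.net[i],
                "percent": 100.0 * state.net[i] / ref,
                "percent_sd": 100.0 * sds.get(r.id, np.nan) / abs(ref)
                if sds
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def normalize_map(fit: FitResult, reference: str = "pts", sds: dict[str, float] | None = None) -> pd.DataFrame:
    return normalize_state(fit.state, reference, sds)


@dataclass
class NadphBalance:
    oxppp_percent: float
    icd_percent: float
    mez_percent: float
    production_percent: float
    requirement_percent: float
    gap_percent: float


def nadph_balance(
    normalized: dict[str, float] | pd.DataFrame,
    mu: float,
    nadph_coefficient: float = 14849.0,
    v_glc: float | None = None,
) -> NadphBalance:
    """NADPH source/sink accounting on a normalized flux map.

    ``normalized`` maps reaction id -> percent of glucose uptake (gnd, icd,
    mez needed). Production = 2 x gnd + icd + mez (the oxidative PPP yields
    two NADPH per G6P). The growth requirement is the NADPH biomass
    coefficient (micromol/gCDW) times mu, as a percent of the glucose
    uptake rate ``v_glc`` (micromol/gCDW/h).
    """
    if isinstance(normalized, pd.DataFrame):
        normalized = dict(zip(normalized["reaction"], normalized["percent"]))
    gnd = normalized.get("gnd", 0.0)
    icd = normalized.get("icd", 0.0)
    mez = normalized.get("mez", 0.0)
    production = 2.0 * gnd + icd + mez
    if v_glc is None:
        raise ValueError("v_glc (absolute glucose uptake) is required")
    requirement = 100.0 * nadph_coefficient * mu / v_glc
    return NadphBalance(
        oxppp_percent=2.0 * gnd,
        icd_percent=icd,
        mez_percent=mez,
        production_percent=production,
        requirement_percent=requirement,
        gap_percent=requirement - production,
    )


def nadph_production_from_annotations(model: NetworkModel, normalized: dict[str, float]) -> float:
    """Total NADPH production (% of uptake) from reaction cofactor annotations."""
    return sum(
        r.nadph * normalized.get(r.id, 0.0)
        for r in model.reactions
        if r.nadph > 0
    )


@dataclass
class CarbonBalance:
    biomass_percent: float
    co2_percent: float
    co2_per_glucose: float
    residual_percent: float


def carbon_balance(state: FluxState, glucose_uptake: str = "pts", co2_export: str = "co2_ex") -> CarbonBalance:
    """Carbon-weighted output fractions of a steady-state flux map.

    Inputs are the carbon uptake fluxes (glucose, protocatechuate); outputs
    are biomass drains and CO2 export. On a product-free network the
    biomass and CO2 percentages sum to 100; a residual above 1 percent
    triggers a warning.
    """
    model = state.model
    carbon_in = 0.0
    for i, r in enumerate(model.reactions):
        for met, _ in r.educts:
            if model.metabolites[met].role == "input":
                carbon_in += state.net[i] * model.metabolites[met].n_carbons
    bm_c = 0.0
    for i, r in enumerate(model.reactions):
        if r.is_drain:
            for met, letters in r.educts:
                bm_c += state.net[i] * model.metabolites[met].n_carbons
    co2_c = state.net_of(co2_export)
    glc = state.net_of(glucose_uptake)
    residual = 100.0 * (carbon_in - bm_c - co2_c) / carbon_in
    if abs(residual) > 1.0:
        import warnings

        warnings.warn(f"carbon imbalance {residual:.2f}%", RuntimeWarning)
    return CarbonBalance(
        biomass_percent=100.0 * bm_c / carbon_in,
        co2_percent=100.0 * co2_c / carbon_in,
        co2_per_glucose=co2_c / glc if glc else 0.0,
        residual_percent=residual,
    )


def co2_per_glucose_from_fraction(co2_fraction: float) -> float:
    """Mol CO2 per mol glucose implied by a fractional carbon split."""
    return 6.0 * co2_fraction
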