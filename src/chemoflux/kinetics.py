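"""Chemostat balances, Pirt maintenance regression, and the bioprocess model.

At metabolic steady state in a chemostat the dilution rate D fixes the
growth rate (mu = D), and with residual substrate below detection the
biomass-specific glucose consumption and yield follow directly from feed
concentration and biomass density:

    q_GLC = D * c_feed / c_X        (g / gCDW / h)
    Y_X,GLC = D / q_GLC = c_X / c_feed

Across dilution rates, substrate uptake decomposes into growth-coupled and
maintenance terms (Pirt): q = mu / Y_real + m_S, estimated by ordinary
least squares on (mu, q) pairs in mmol/gCDW/h.

For transient data, an ODE bioprocess model (biomass and substrate balances
with Monod kinetics and Pirt uptake) is fitted by weighted least squares;
parameter uncertainty comes from parametric-bootstrap Monte-Carlo
replicates, each restarted from randomized initial parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import solve_ivp

GLUCOSE_MOLAR_MASS = 180.16  # g/mol
BIOMASS_CARBON = 0.48        # g carbon per g CDW, configurable default
AIR_O2 = 0.2094
AIR_CO2 = 0.0004


@dataclass(frozen=True)
class ChemostatObservation:
    """One steady-state chemostat operating point."""

    D: float                 # dilution rate, 1/h
    c_X: float               # biomass, g CDW / L
    c_glc_feed: float        # feed glucose, g / L
    y_o2_in: float = AIR_O2      # inlet O2 mole fraction
    y_co2_in: float = AIR_CO2    # inlet CO2 mole fraction
    y_o2_out: float | None = None
    y_co2_out: float | None = None
    gas_flow: float | None = None  # inlet gas flow, mol / h
    volume: float = 1.0            # culture volume, L
    tic: float = 0.0               # total inorganic carbon in broth, mmol / L
    replicate: str = ""

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("negative dilution rate")
        if self.c_X <= 0:
            raise ValueError("non-positive biomass concentration")


def growth_rate(obs: ChemostatObservation) -> float:
    """mu = D at metabolic steady state."""
    return obs.D


def specific_glucose_uptake(obs: ChemostatObservation) -> float:
    """q_GLC = D * c_feed / c_X in g/gCDW/h (residual glucose negligible)."""
    return obs.D * obs.c_glc_feed / obs.c_X


def biomass_yield(obs: ChemostatObservation) -> float:
    """Y_X,GLC = c_X / c_feed (g/g); algebraically equal to D / q_GLC."""
    if obs.c_glc_feed <= 0:
        raise ValueError("non-positive feed concentration")
    return obs.c_X / obs.c_glc_feed


def respiratory_rates(obs: ChemostatObservation) -> tuple[float, float]:
    """Biomass-specific O2 uptake and CO2 evolution rates (mmol/gCDW/h).

    Molar balance over the gas phase with inert-gas (N2) correction of the
    outlet flow; the CO2 evolution rate is augmented by the dissolved
    inorganic carbon carried out with the liquid (D * TIC / c_X).
    Raises if the outlet O2 fraction exceeds the inlet (impossible
    consumption).
    """
    if obs.y_o2_out is None or obs.y_co2_out is None or obs.gas_flow is None:
        raise ValueError("gas composition/flow data missing")
    if obs.y_o2_out > obs.y_o2_in + 1e-12:
        raise ValueError("outlet O2 above inlet O2")
    inert_in = 1.0 - obs.y_o2_in - obs.y_co2_in
    inert_out = 1.0 - obs.y_o2_out - obs.y_co2_out
    f_out = obs.gas_flow * inert_in / inert_out
    n_o2 = obs.gas_flow * obs.y_o2_in - f_out * obs.y_o2_out     # mol/h consumed
    n_co2 = f_out * obs.y_co2_out - obs.gas_flow * obs.y_co2_in  # mol/h produced
    denom = obs.volume * obs.c_X
    q_o2 = 1000.0 * n_o2 / denom
    q_co2 = 1000.0 * n_co2 / denom + obs.D * obs.tic / obs.c_X
    return q_o2, q_co2


def respiratory_quotient(q_o2: float, q_co2: float) -> float:
    return q_co2 / q_o2


@dataclass
class PirtResult:
    m_s: float              # mmol glucose / gCDW / h, maintenance
    inv_y_real: float       # mmol glucose / gCDW, growth-coupled slope
    m_s_se: float
    inv_y_real_se: float

    @property
    def y_real(self) -> float:
        return 1.0 / self.inv_y_real


def pirt_regression(points: list[tuple[float, float]]) -> PirtResult:
    """OLS of q_GLC (mmol/gCDW/h) on mu: q = (1/Y_real) mu + m_S."""
    mus = np.array([p[0] for p in points], float)
    qs = np.array([p[1] for p in points], float)
    if np.unique(mus).size < 2:
        raise ValueError("need at least two distinct growth rates")
    res = stats.linregress(mus, qs)
    return PirtResult(
        m_s=float(res.intercept),
        inv_y_real=float(res.slope),
        m_s_se=float(res.intercept_stderr),
        inv_y_real_se=float(res.stderr),
    )


def q_glc_mmol(obs: ChemostatObservation) -> float:
    """Specific glucose uptake in mmol/gCDW/h."""
    return 1000.0 * specific_glucose_uptake(obs) / GLUCOSE_MOLAR_MASS


# ---------------------------------------------------------------------------
# reference chemostat dataset (triplicate steady states and labeling phase)
# ---------------------------------------------------------------------------

#: steady-state process table of the triplicate chemostat study:
#: D (1/h), c_X (g/L), q_GLC (g/g/h), Y_XS (g/g), q_O2 and q_CO2 (mmol/g/h),
#: at a feed of 12.47 g glucose / L.
CHEMOSTAT_TABLE = pd.DataFrame(
    [
        {"D": 0.20, "c_X": 5.87, "q_glc": 0.42, "y_xs": 0.47, "q_o2": 5.36, "q_co2": 5.64},
        {"D": 0.30, "c_X": 6.09, "q_glc": 0.62, "y_xs": 0.49, "q_o2": 7.16, "q_co2": 7.30},
        {"D": 0.40, "c_X": 6.43, "q_glc": 0.77, "y_xs": 0.52, "q_o2": 8.15, "q_co2": 7.94},
    ]
)
CHEMOSTAT_FEED = 12.47  # g glucose / L

#: process parameters of the labeling experiment (D = 0.4 1/h):
#: unlabeled and labeled feed phases.
LABELING_TABLE = pd.DataFrame(
    [
        {"phase": "12C", "q_glc": 0.74, "q_o2": 9.26, "q_co2": 9.86, "c_glc_feed": 11.32, "c_X": 6.09},
        {"phase": "13C", "q_glc": 0.77, "q_o2": 9.77, "q_co2": float("nan"), "c_glc_feed": 11.88, "c_X": 6.20},
    ]
)


# ---------------------------------------------------------------------------
# ODE bioprocess model
# ---------------------------------------------------------------------------

@dataclass
class BioprocessParams:
    """Chemostat ODE parameters: Monod growth, Pirt uptake, feed schedule."""

    mu_max: float = 0.44          # 1/h
    k_s: float = 0.05             # g/L Monod constant for growth
    k_m: float = 5e-4             # g/L saturation constant of maintenance uptake
    inv_y_real: float = 9.73      # mmol glucose / gCDW (growth-coupled)
    m_s: float = 0.44             # mmol glucose / gCDW / h (maintenance)
    s_feed: float = 12.47         # g/L
    x0: float = 0.3               # g/L inoculum
    s0: float = 12.0              # g/L initial glucose
    pca_feed_umol: float = 195.0  # micromol PCA / L in feed
    biomass_carbon: float = BIOMASS_CARBON

    def q_glc(self, mu: float) -> float:
        """Specific glucose uptake (g/g/h) at growth rate mu."""
        return (self.inv_y_real * mu + self.m_s) * GLUCOSE_MOLAR_MASS / 1000.0


def _rhs(t, y, p: BioprocessParams, D_of_t):
    X, S = np.maximum(y, 0.0)
    D = D_of_t(t)
    mu = p.mu_max * S / (p.k_s + S)
    # maintenance saturates at trace substrate levels (k_m << k_s): flat over
    # chemostat operating points, but vanishing at S = 0 so S stays >= 0
    q = (p.inv_y_real * mu + p.m_s * S / (p.k_m + S)) * GLUCOSE_MOLAR_MASS / 1000.0
    dX = (mu - D) * X
    dS = D * (p.s_feed - S) - q * X
    return [dX, dS]


def simulate_bioprocess(
    params: BioprocessParams,
    schedule: list[tuple[float, float]],
    t_end: float,
    t_eval: np.ndarray | None = None,
) -> pd.DataFrame:
    """Integrate the chemostat ODEs under a dilution-rate schedule.

    ``schedule`` is a list of (start time, D) segments; D = 0 gives batch
    operation. Returns time, biomass X, substrate S, D, growth rate and the
    derived specific rates.
    """
    def D_of_t(t):
        d = 0.0
        for ts, dv in sorted(schedule):
            if t >= ts:
                d = dv
        return d

    # integrate piecewise between dilution-rate switches (D is constant
    # within a segment, so the stiff solver can take large steps)
    edges = sorted({0.0, t_end, *(ts for ts, _ in schedule if 0.0 < ts < t_end)})
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 400)
    t_eval = np.asarray(t_eval, float)
    ts_all, ys = [], []
    y = [params.x0, params.s0]
    for a, b_ in zip(edges[:-1], edges[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b_)]
        seg_eval = np.unique(np.concatenate([[a], seg_eval, [b_]]))
        d_const = D_of_t(a)
        sol = solve_ivp(
            _rhs,
            (a, b_),
            y,
            args=(params, lambda t, d=d_const: d),
            t_eval=seg_eval,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"bioprocess ODE solver failed: {sol.message}")
        y = sol.y[:, -1]
        keep = np.isin(sol.t, t_eval)
        ts_all.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    t_out = np.concatenate(ts_all)
    Y = np.concatenate(ys, axis=1)
    # drop duplicated segment edges
    t_out, uniq = np.unique(t_out, return_index=True)
    X, S = Y[0, uniq], Y[1, uniq]
    D = np.array([D_of_t(t) for t in t_out])
    mu = params.mu_max * S / (params.k_s + S)
    q = np.array([params.q_glc(m) for m in mu])
    q_co2 = 1000.0 * (
        6.0 * q / GLUCOSE_MOLAR_MASS - mu * params.biomass_carbon / 12.011
    )
    return pd.DataFrame(
        {"time": t_out, "X": X, "S": S, "D": D, "mu": mu, "q_glc": q, "q_co2": q_co2}
    )


@dataclass
class RateEstimate:
    mu: float
    r_glc: float            # micromol / gCDW / h
    r_co2: float
    r_pca: float
    mu_sd: float = 0.0
    r_glc_sd: float = 0.0
    r_co2_sd: float = 0.0
    r_pca_sd: float = 0.0


def _fit_once(series: pd.DataFrame, p0: BioprocessParams, schedule, weights,
              xtol: float = 1e-13, max_nfev: int = 400):
    wx, ws = weights

    def residuals(theta):
        p = replace(
            p0,
            mu_max=theta[0],
            k_s=abs(theta[1]),
            inv_y_real=theta[2],
            m_s=theta[3],
        )
        try:
            sim = simulate_bioprocess(
                p, schedule, float(series["time"].iloc[-1]), series["time"].to_numpy()
            )
        except RuntimeError:
            return np.full(2 * len(series), 1e3)
        return np.concatenate(
            [
                (sim["X"].to_numpy() - series["X"].to_numpy()) / wx,
                (sim["S"].to_numpy() - series["S"].to_numpy()) / ws,
            ]
        )

    theta0 = np.array([p0.mu_max, p0.k_s, p0.inv_y_real, p0.m_s])
    res = optimize.least_squares(
        residuals,
        theta0,
        bounds=([0.05, 1e-4, 1.0, 0.0], [1.5, 1.0, 30.0, 3.0]),
        xtol=xtol,
        ftol=xtol * 10,
        gtol=1e-14,
        max_nfev=max_nfev,
        x_scale=[0.1, 0.02, 1.0, 0.1],
    )
    if not res.success and res.status <= 0:
        raise RuntimeError(f"bioprocess fit did not converge: {res.message}")
    return res.x


def fit_bioprocess(
    series: pd.DataFrame,
    params0: BioprocessParams,
    schedule: list[tuple[float, float]],
    n_mc: int = 100,
    seed: int = 0,
    noise: tuple[float, float] = (0.1, 0.1),
) -> tuple[RateEstimate, BioprocessParams]:
    """Weighted least-squares fit of the bioprocess ODE model.

    ``series`` needs columns time, X, S covering at least one residence
    time. Parameter SDs are the dispersion over ``n_mc`` parametric
    bootstrap replicates (measurement noise resampled at the given SDs,
    each refit from randomly perturbed initial parameter values).
    Deterministic for a given seed. Returns the biomass-specific rate
    estimates at the final dilution rate plus the fitted parameters.
    """
    D_final = [d for _, d in sorted(schedule)][-1]
    span = series["time"].iloc[-1] - series["time"].iloc[0]
    if D_final > 0 and span < 1.0 / D_final:
        raise ValueError("series must cover at least one residence time")
    rng = np.random.default_rng(seed)
    theta = _fit_once(series, params0, schedule, noise)

    def rates_from(thetav) -> np.ndarray:
        p = replace(
            params0,
            mu_max=thetav[0],
            k_s=abs(thetav[1]),
            inv_y_real=thetav[2],
            m_s=thetav[3],
        )
        sim = simulate_bioprocess(
            p, schedule, float(series["time"].iloc[-1]), series["time"].to_numpy()
        )
        mu = float(sim["mu"].iloc[-1])
        q = p.q_glc(mu)
        r_glc = 1e6 * q / GLUCOSE_MOLAR_MASS
        r_co2 = float(sim["q_co2"].iloc[-1]) * 1000.0
        x_ss = float(sim["X"].iloc[-1])
        r_pca = D_final * p.pca_feed_umol / x_ss if x_ss > 0 else 0.0
        return np.array([mu, r_glc, r_co2, r_pca])

    base = rates_from(theta)
    boots = []
    sim0 = None
    p_best = replace(
        params0, mu_max=theta[0], k_s=abs(theta[1]), inv_y_real=theta[2], m_s=theta[3]
    )
    sim0 = simulate_bioprocess(
        p_best, schedule, float(series["time"].iloc[-1]), series["time"].to_numpy()
    )
    for _ in range(n_mc):
        fake = series.copy()
        fake["X"] = sim0["X"].to_numpy() + rng.normal(0, noise[0], len(series))
        fake["S"] = np.maximum(
            sim0["S"].to_numpy() + rng.normal(0, noise[1], len(series)), 0.0
        )
        p_start = replace(
            params0,
            mu_max=params0.mu_max * rng.uniform(0.7, 1.3),
            inv_y_real=params0.inv_y_real * rng.uniform(0.7, 1.3),
            m_s=max(params0.m_s * rng.uniform(0.5, 1.5), 1e-3),
        )
        try:
            th = _fit_once(fake, p_start, schedule, noise, xtol=1e-8, max_nfev=120)
            boots.append(rates_from(th))
        except RuntimeError:
            continue
    sds = np.std(boots, axis=0, ddof=1) if len(boots) > 1 else np.zeros(4)
    est = RateEstimate(
        mu=base[0], r_glc=base[1], r_co2=base[2], r_pca=base[3],
        mu_sd=sds[0], r_glc_sd=sds[1], r_co2_sd=sds[2], r_pca_sd=sds[3],
    )
    return est, p_best


def carbon_recovery(
    obs: ChemostatObservation,
    q_co2: float,
    toc_out: float = 0.0,
    pca_feed_umol: float = 0.0,
    biomass_carbon: float = BIOMASS_CARBON,
) -> float:
    """Percent carbon recovered: (biomass C + CO2 C + TOC) / fed C."""
    c_in = (
        obs.D * obs.c_glc_feed / GLUCOSE_MOLAR_MASS * 6.0 * 1000.0
        + obs.D * pca_feed_umol * 7.0 / 1000.0
    )  # mmol C / L / h
    c_bm = obs.D * obs.c_X * biomass_carbon / 12.011 * 1000.0
    c_co2 = q_co2 * obs.c_X
    c_toc = obs.D * toc_out
    return 100.0 * (c_bm + c_co2 + c_toc) / c_in
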