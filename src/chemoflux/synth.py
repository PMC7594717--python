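"""Synthetic ground-truth data with the statistical structure of the study.

The generator emulates the labeling experiment's measurement configuration:
164 mass isotopomer fractions over the 28-metabolite panel (independent
Gaussian noise, flat SD 2.5 mol%, truncated to [0,1] and renormalized) and
biomass-specific extracellular rates with their reported SDs. Ground truth
is stored alongside so simulate-then-fit closure, SSR calibration and
interval coverage are all testable offline.

The ``paper_flux_map`` preset pins the free fluxes to the study's fitted
chemostat state at D = 0.4 1/h (glucose uptake 4,086 micromol/gCDW/h,
growth rate 0.41 1/h, one third of glucose through the oxidative PPP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chemoflux.fitting import FitDataset, FluxFitProblem, RateMeasurement
from chemoflux.kinetics import BioprocessParams, simulate_bioprocess
from chemoflux.mids import (
    DEFAULT_MID_SD,
    Fragment,
    MIDMeasurement,
    PAPER_MIXTURE,
    TracerMixture,
    load_panel,
)
from chemoflux.network import FluxBasis, FluxState, NetworkModel, unit_to_exchange


# free net fluxes of the study-state preset (micromol/gCDW/h; mu in 1/h)
PAPER_FREE_NET = {
    "pts": 4086.0,
    "pca_upt": 13.0,
    "__mu__": 0.41,
    "zwf": 1291.0,
    "pyc": 1279.0,
    "pck": 150.0,
    "mez": 50.0,
}

# moderate exchange fluxes for the preset (micromol/gCDW/h)
PAPER_EXCHANGE = {
    "pgi": 1500.0, "fba": 500.0, "tpi": 800.0, "gapA": 1000.0, "eno": 1000.0,
    "rpe": 400.0, "rpi": 300.0, "tkt1": 150.0, "tal": 150.0, "tkt2": 150.0,
    "acn": 500.0, "sucCD": 100.0, "sdh": 200.0, "fumh": 800.0, "mdh": 1500.0,
    "gdh": 500.0, "aspB": 300.0, "alaT": 300.0, "serA": 100.0, "glyA": 100.0,
}

# measured extracellular rates of the labeling experiment (value, SD)
PAPER_RATES = {
    "mu": (0.40, 0.03),
    "pts": (4130.0, 150.0),
    "co2_ex": (8240.0, 760.0),
    "pca_upt": (13.0, 1.0),
}


def paper_flux_state(basis: FluxBasis) -> FluxState:
    """The bundled study-conditions flux preset ('paper_flux_map')."""
    free = [PAPER_FREE_NET[k] for k in basis.free_net]
    exch = [PAPER_EXCHANGE.get(r, 0.0) for r in basis.free_exchange]
    return basis.realize(free, exch)


def sample_true_fluxes(
    basis: FluxBasis,
    seed: int = 0,
    box: dict[str, tuple[float, float]] | None = None,
    exchange_t_max: float = 0.8,
    exchange_scale: float = 1000.0,
    max_tries: int = 2000,
    preset: str | None = None,
) -> FluxState:
    """Draw a feasible ground-truth FluxState.

    Free net fluxes are sampled uniformly in their boxes and rejected until
    every unidirectional net flux is non-negative; free exchanges are
    sampled on the bounded transform. ``preset='paper_flux_map'`` returns
    the deterministic study-state instead.
    """
    if preset == "paper_flux_map":
        return paper_flux_state(basis)
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    from chemoflux.fitting import DEFAULT_NET_BOUNDS

    rng = np.random.default_rng(seed)
    merged = {**DEFAULT_NET_BOUNDS, **(box or {})}
    uni = np.array([not r.bidirectional for r in basis.model.reactions])
    for _ in range(max_tries):
        free = np.array(
            [rng.uniform(*merged.get(n, (-2000.0, 2000.0))) for n in basis.free_net]
        )
        ts = rng.uniform(0.0, exchange_t_max, len(basis.free_exchange))
        state = basis.realize(free, unit_to_exchange(ts, exchange_scale))
        if np.all(state.net[uni] >= 0):
            return state
    raise RuntimeError(f"no feasible flux state found in {max_tries} draws")


@dataclass
class SyntheticScenario:
    """Everything needed to generate one reproducible synthetic dataset."""

    model: NetworkModel
    basis: FluxBasis
    true_state: FluxState
    mixture: TracerMixture = PAPER_MIXTURE
    mid_sd: float = DEFAULT_MID_SD       # noise amplitude, mol fraction
    weight_sd: float | None = None       # assumed SD for weighting (defaults sanely)
    rate_defs: dict[str, tuple[float, float]] | None = None  # name -> (sim?, sd)
    panel: list[Fragment] | None = None
    seed: int = 0

    @property
    def assumed_sd(self) -> float:
        if self.weight_sd is not None:
            return self.weight_sd
        return self.mid_sd if self.mid_sd > 0 else DEFAULT_MID_SD


def simulate_dataset(scenario: SyntheticScenario) -> tuple[FitDataset, dict]:
    """Generate a noisy measurement dataset plus its ground truth.

    MIDs are simulated at the true flux state, perturbed with independent
    Gaussian noise of the scenario SD, truncated to [0, 1] and
    renormalized. Rate measurements are the true simulated rates plus
    Gaussian noise at the stated SDs. Identical seeds give identical
    datasets.
    """
    model = scenario.model
    panel = scenario.panel if scenario.panel is not None else load_panel()
    rng = np.random.default_rng(scenario.seed)

    problem_ds = FitDataset(
        mids=[
            MIDMeasurement(
                fragment=f,
                mid=np.zeros(model.metabolites[f.pool or f.metabolite].n_carbons + 1),
                sd=scenario.assumed_sd,
                group=f.metabolite,
            )
            for f in panel
        ],
        rates=[],
        mixture=scenario.mixture,
    )
    problem = FluxFitProblem(model, problem_ds, basis=scenario.basis)
    sim_mids, _ = problem.simulate_measurements(scenario.true_state)

    noisy = []
    for f, sim in zip(panel, sim_mids):
        mid = sim + (rng.normal(0.0, scenario.mid_sd, sim.shape) if scenario.mid_sd else 0.0)
        mid = np.clip(mid, 0.0, 1.0)
        mid = mid / mid.sum()
        noisy.append(
            MIDMeasurement(fragment=f, mid=mid, sd=scenario.assumed_sd, group=f.metabolite)
        )

    rate_defs = scenario.rate_defs or {k: (None, sd) for k, (_, sd) in PAPER_RATES.items()}
    rates = []
    truth_rates = {}
    for name, (value, sd) in rate_defs.items():
        true_val = (
            scenario.true_state.mu
            if name == "mu"
            else scenario.true_state.net_of(name)
        ) if value is None else value
        truth_rates[name] = true_val
        noise = rng.normal(0.0, sd) if scenario.mid_sd else 0.0
        rates.append(RateMeasurement(name=name, value=true_val + noise, sd=sd))

    dataset = FitDataset(mids=noisy, rates=rates, mixture=scenario.mixture)
    truth = {
        "free_net": dict(
            zip(scenario.basis.free_net, scenario.basis.extract_free(scenario.true_state))
        ),
        "rates": truth_rates,
        "seed": scenario.seed,
    }
    return dataset, truth


def simulate_chemostat(
    params: BioprocessParams,
    schedule: list[tuple[float, float]],
    t_end: float,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    n_samples: int = 200,
) -> pd.DataFrame:
    """Chemostat process time series: batch, wash-in and steady state.

    Integrates the bioprocess ODEs under the dilution schedule and adds
    Gaussian observation noise (biomass SD, substrate SD) to the sampled
    trajectory. The returned frame carries noisy X, S plus the noise-free
    trajectory columns (X_true, S_true).
    """
    if params.x0 <= 0:
        raise ValueError("positive initial biomass required")
    t_eval = np.linspace(0.0, t_end, n_samples)
    sim = simulate_bioprocess(params, schedule, t_end, t_eval)
    rng = np.random.default_rng(seed)
    out = sim.rename(columns={"X": "X_true", "S": "S_true"})
    out["X"] = out["X_true"] + rng.normal(0.0, noise[0], len(out))
    out["S"] = np.maximum(out["S_true"] + rng.normal(0.0, noise[1], len(out)), 0.0)
    return out


def dataset_to_csv(dataset: FitDataset, truth: dict, out_prefix: str) -> None:
    """Write a dataset as measurement CSV + ground-truth JSON."""
    from chemoflux.mids import measurements_to_frame

    measurements_to_frame(dataset.mids).to_csv(f"{out_prefix}_mids.csv", index=False)
    pd.DataFrame(
        [{"name": r.name, "value": r.value, "sd": r.sd} for r in dataset.rates]
    ).to_csv(f"{out_prefix}_rates.csv", index=False)
    with open(f"{out_prefix}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
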