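"""Weighted SSR objective, chi-square acceptance, intervals, accounting."""

import numpy as np
import pandas as pd
import pytest

from chemoflux.fitting import (
    FitConfig,
    FitDataset,
    FluxFitProblem,
    RateMeasurement,
    chi2_acceptance,
    carbon_balance,
    confidence_intervals,
    co2_per_glucose_from_fraction,
    fit_fluxes,
    nadph_balance,
    nadph_production_from_annotations,
    normalize_state,
    weighted_ssr,
)
from chemoflux.mids import Fragment, MIDMeasurement, TracerMixture
from chemoflux.network import build_flux_basis, load_network
from chemoflux.synth import SyntheticScenario, paper_flux_state, simulate_dataset

from conftest import BRANCH, BRANCH_NONIDENT


TOY_MIXTURE = TracerMixture(
    (((1, 1, 1, 1, 1, 1), 0.5), ((0, 0, 0, 0, 0, 0), 0.5))
)


def branch_dataset(model, state, noise=0.0, seed=0, sd=0.02):
    """Noisy MIDs of pools A and B plus the uptake rate measurement."""
    from chemoflux.emu import decompose, full_emu, simulate_mids

    rng = np.random.default_rng(seed)
    targets = [full_emu(model, "A"), full_emu(model, "B")]
    system = decompose(model, targets)
    # 3-carbon input: half uniformly 13C-labeled, half unlabeled
    tensor = np.zeros((2, 2, 2))
    tensor[(0, 0, 0)] = 0.5
    tensor[(1, 1, 1)] = 0.5
    from conftest import tensor_mid

    tracer = {e: tensor_mid(tensor, e.atoms) for e in system.input_emus}
    sim = simulate_mids(system, state, tracer)
    mids = []
    for pool in ("A", "B"):
        mid = sim[full_emu(model, pool)].copy()
        mid = np.clip(mid + rng.normal(0, noise, mid.shape), 0, 1)
        mid /= mid.sum()
        mids.append(
            MIDMeasurement(
                fragment=Fragment(pool, 3, {"C": 3}, pool), mid=mid, sd=sd, group=pool
            )
        )
    rates = [
        RateMeasurement("upt", state.net_of("upt") + rng.normal(0, noise * 10), 0.2),
        RateMeasurement("outa", state.net_of("outa") + rng.normal(0, noise * 10), 0.2),
    ]
    return FitDataset(mids=mids, rates=rates, mixture=TOY_MIXTURE), tracer


class BranchTracerProblem(FluxFitProblem):
    """FluxFitProblem bound to the toy 3-carbon tracer instead of glucose."""

    def __init__(self, model, dataset, tracer, **kw):
        super().__init__(model, dataset, **kw)
        self.tracer = {e: tracer[e] for e in self.system.input_emus}


@pytest.fixture
def branch_problem():
    model = load_network(BRANCH)
    basis = build_flux_basis(model)
    # truth: upt 10, split p1 6 / p2 4, iso net 1 with exchange 2
    free = {"upt": 10.0, "p1": 6.0, "iso": 1.0}
    truth = basis.realize([free[n] for n in basis.free_net], [2.0])
    ds, tracer = branch_dataset(model, truth, noise=0.0)
    cfg = FitConfig(
        net_bounds={"upt": (1.0, 30.0), "p1": (0.0, 30.0), "iso": (-10.0, 10.0)},
        exchange_scale=5.0,
        n_kicks=4,
    )
    problem = BranchTracerProblem(model, ds, tracer, basis=basis, config=cfg)
    return problem, truth


class TestWeightedSSR:
    def test_zero_at_truth_for_noise_free_data(self, branch_problem):
        problem, truth = branch_problem
        theta = problem.theta_from_state(truth)
        assert weighted_ssr(theta, problem.dataset, problem) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_single_rate_contributes_squared_standardized_residual(self, branch_problem):
        problem, truth = branch_problem
        theta = problem.theta_from_state(truth)
        theta = theta.copy()
        # shift the uptake by 0.1 -> rate residual (0.1/0.2)^2 plus tiny MID terms
        i = problem.basis.free_net.index("upt")
        base = problem.ssr(theta)
        theta[i] += 0.1
        # recompute the exact expectation from the residual vector
        res = problem.residuals(theta, with_penalty=False)
        rate_term = res[8] ** 2  # the uptake-rate slot (after 2 x 4 MID entries)
        assert rate_term == pytest.approx((0.1 / 0.2) ** 2, rel=1e-9)
        assert base == pytest.approx(0.0, abs=1e-18)

    def test_ssr_of_noisy_data_near_expected_scale(self, bundled_model, bundled_basis):
        truth = paper_flux_state(bundled_basis)
        sc = SyntheticScenario(
            model=bundled_model, basis=bundled_basis, true_state=truth,
            mid_sd=0.025, seed=3,
        )
        ds, _ = simulate_dataset(sc)
        problem = FluxFitProblem(bundled_model, ds, basis=bundled_basis)
        ssr = problem.ssr(problem.theta_from_state(truth))
        # scale-projected expectation ~ (164 - 28) + 4 with wide tolerance
        assert 60 < ssr < 240


class TestChi2:
    def test_alpha_one_gives_zero(self):
        assert chi2_acceptance(170, 55, alpha=1.0) == 0.0

    def test_quantile_matches_numerical_integration(self):
        # independent oracle: integrate the chi2 density and invert
        from scipy.integrate import quad
        from scipy.optimize import brentq
        from scipy.special import gamma

        dof = 115

        def pdf(x):
            return x ** (dof / 2 - 1) * np.exp(-x / 2) / (
                2 ** (dof / 2) * gamma(dof / 2)
            )

        def cdf(x):
            return quad(pdf, 0, x, limit=200)[0]

        q = brentq(lambda x: cdf(x) - 0.95, 50, 250, xtol=1e-8)
        assert chi2_acceptance(170, 55, 0.05) == pytest.approx(q, abs=1e-4)
        assert chi2_acceptance(170, 55, 0.05) == pytest.approx(141.0, abs=0.05)

    def test_threshold_increases_with_dof(self):
        prev = 0.0
        for dof in (5, 20, 80, 115, 300):
            cur = chi2_acceptance(dof + 10, 10, 0.05)
            assert cur > prev
            prev = cur

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            chi2_acceptance(10, 10)


class TestFitFluxes:
    def test_noise_free_recovery_on_toy(self, branch_problem):
        problem, truth = branch_problem
        fit = fit_fluxes(problem, n_starts=5, seed=2)
        th_true = problem.theta_from_state(truth)
        k = len(problem.basis.free_net)
        assert fit.ssr < 1e-12
        np.testing.assert_allclose(fit.theta[:k], th_true[:k], rtol=1e-4, atol=1e-4)

    def test_more_starts_never_worse(self, branch_problem):
        problem, _ = branch_problem
        cfg = problem.config
        cfg.n_kicks = 0
        one = fit_fluxes(problem, n_starts=1, seed=9)
        many = fit_fluxes(problem, n_starts=10, seed=9)
        assert many.ssr <= one.ssr + 1e-9

    def test_requires_at_least_one_start(self, branch_problem):
        problem, _ = branch_problem
        with pytest.raises(ValueError):
            fit_fluxes(problem, n_starts=0)

    def test_report_counts_scales_as_parameters(self, branch_problem):
        problem, _ = branch_problem
        fit = fit_fluxes(problem, n_starts=2, seed=4)
        # 3 free nets + 1 exchange + 2 group scales
        assert fit.n_params == 6
        assert fit.n_meas == 10  # 2 x 4 MID entries + 2 rates
        assert fit.dof == 4
        assert fit.accepted
        assert isinstance(fit.residuals, pd.DataFrame)
        assert len(fit.trace) >= 2


class TestConfidenceIntervals:
    def test_interval_widths_shrink_with_noise(self):
        model = load_network(BRANCH)
        basis = build_flux_basis(model)
        truth = basis.realize([10.0, 6.0, 1.0][: len(basis.free_net)], [2.0])
        widths = []
        for sd in (0.04, 0.004):
            ds, tracer = branch_dataset(model, truth, noise=0.0, sd=sd)
            cfg = FitConfig(
                net_bounds={"upt": (1.0, 30.0), "p1": (0.0, 30.0), "iso": (-10, 10)},
                exchange_scale=5.0, n_kicks=0,
            )
            problem = BranchTracerProblem(model, ds, tracer, basis=basis, config=cfg)
            fit = fit_fluxes(problem, n_starts=3, seed=1)
            ci = confidence_intervals(fit, mode="profile", params=["p1"])[0]
            assert not ci.non_identifiable
            widths.append(ci.upper - ci.lower)
        assert widths[1] < 0.25 * widths[0]

    def test_structurally_undetermined_flux_flagged(self):
        model = load_network(BRANCH_NONIDENT)
        basis = build_flux_basis(model)
        # p1/p3 carry identical atom maps: only their sum is determined
        free = {"upt": 10.0, "p1": 4.0, "p3": 3.0, "iso": 1.0}
        truth = basis.realize(
            [free[n] for n in basis.free_net],
            [2.0] * len(basis.free_exchange),
        )
        ds, tracer = branch_dataset(model, truth, noise=0.0)
        cfg = FitConfig(
            net_bounds={n: (0.0, 30.0) for n in basis.free_net}, n_kicks=0,
        )
        problem = BranchTracerProblem(model, ds, tracer, basis=basis, config=cfg)
        fit = fit_fluxes(problem, n_starts=3, seed=1)
        target = "p1" if "p1" in basis.free_net else "p3"
        ci = confidence_intervals(fit, mode="profile", params=[target])[0]
        assert ci.non_identifiable

    def test_linearized_close_to_profile_on_near_linear_problem(self):
        model = load_network(BRANCH)
        basis = build_flux_basis(model)
        truth = basis.realize([10.0, 6.0, 1.0][: len(basis.free_net)], [2.0])
        ds, tracer = branch_dataset(model, truth, noise=0.005, seed=3, sd=0.02)
        cfg = FitConfig(
            net_bounds={"upt": (1.0, 30.0), "p1": (0.0, 30.0), "iso": (-10, 10)},
            exchange_scale=5.0, n_kicks=0,
        )
        problem = BranchTracerProblem(model, ds, tracer, basis=basis, config=cfg)
        fit = fit_fluxes(problem, n_starts=3, seed=1)
        lin = confidence_intervals(fit, mode="linearized", params=["upt"])[0]
        prof = confidence_intervals(fit, mode="profile", params=["upt"])[0]
        w_lin = lin.upper - lin.lower
        w_prof = prof.upper - prof.lower
        assert w_lin == pytest.approx(w_prof, rel=0.2)


class TestAccounting:
    def test_reference_normalizes_to_100(self, paper_state):
        table = normalize_state(paper_state, "pts")
        assert table.set_index("reaction").loc["pts", "percent"] == pytest.approx(100.0)

    def test_percent_arithmetic(self, paper_state):
        table = normalize_state(paper_state, "pts").set_index("reaction")
        assert table.loc["gnd", "percent"] == pytest.approx(
            100 * 1291.0 / 4086.0, rel=1e-9
        )

    def test_sign_preserved_for_reverse_net_flux(self, bundled_basis):
        from chemoflux.synth import PAPER_FREE_NET

        free = dict(PAPER_FREE_NET)
        st = bundled_basis.realize([free[k] for k in bundled_basis.free_net])
        # force a reverse net flux on a bidirectional reaction
        i = st.model.reaction_index["gdh"]
        st.net[i] = -25.0
        table = normalize_state(st, "pts").set_index("reaction")
        assert table.loc["gdh", "percent"] < 0

    def test_normalization_round_trip(self, paper_state):
        table = normalize_state(paper_state, "pts")
        back = table["percent"].to_numpy() * paper_state.net_of("pts") / 100.0
        np.testing.assert_allclose(back, paper_state.net, rtol=1e-9, atol=1e-9)

    def test_nadph_balance_reported_values(self):
        nb = nadph_balance(
            {"gnd": 31.6, "icd": 58.3, "mez": 0.0}, mu=0.41,
            nadph_coefficient=14849.0, v_glc=4086.0,
        )
        assert nb.production_percent == pytest.approx(121.5, abs=0.01)
        assert nb.requirement_percent == pytest.approx(149.0, abs=0.05)
        assert nb.gap_percent == pytest.approx(27.5, abs=0.06)

    def test_nadph_zero_map(self):
        nb = nadph_balance({}, mu=0.4, v_glc=4000.0)
        assert nb.production_percent == 0.0
        assert nb.gap_percent == nb.requirement_percent

    def test_annotation_sum_matches_closed_form(self, bundled_model, paper_state):
        table = normalize_state(paper_state, "pts")
        pct = dict(zip(table["reaction"], table["percent"]))
        total = nadph_production_from_annotations(bundled_model, pct)
        nb = nadph_balance(pct, mu=paper_state.mu, v_glc=paper_state.net_of("pts"))
        assert total == pytest.approx(nb.production_percent, abs=1e-9)

    def test_carbon_balance_on_study_state(self, paper_state):
        cb = carbon_balance(paper_state)
        assert cb.biomass_percent + cb.co2_percent == pytest.approx(100.0, abs=1e-6)
        assert cb.biomass_percent == pytest.approx(65.6, abs=0.5)
        assert cb.co2_per_glucose == pytest.approx(2.06, abs=0.05)

    def test_fraction_to_molar_ratio(self):
        assert co2_per_glucose_from_fraction(0.344) == pytest.approx(2.064)
        assert co2_per_glucose_from_fraction(0.0) == 0.0
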