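"""EMU decomposition and MID simulation against the isotopomer oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemoflux.emu import (
    SimulationError,
    convolve,
    decompose,
    emu,
    full_emu,
    isotopomer_oracle,
    simulate_mids,
)
from chemoflux.network import NetworkError, load_network, build_flux_basis

from conftest import (
    LINEAR_CHAIN,
    TOY_DOCS,
    random_flux_state,
    random_input_tensor,
    tensor_mid,
)


def _input_mids_from_tensors(system, tensors):
    return {e: tensor_mid(tensors[e.met], e.atoms) for e in system.input_emus}


class TestConvolve:
    def test_delta_times_bernoulli(self):
        np.testing.assert_allclose(convolve([1, 0], [0.3, 0.7]), [0.3, 0.7, 0.0])

    def test_binomial(self):
        np.testing.assert_allclose(
            convolve([0.5, 0.5], [0.5, 0.5]), [0.25, 0.5, 0.25]
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=5),
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=5),
    )
    def test_sum_is_product_of_sums(self, a, b):
        c = convolve(a, b)
        assert len(c) == len(a) + len(b) - 1
        assert np.sum(c) == pytest.approx(np.sum(a) * np.sum(b), abs=1e-9)


class TestDecompose:
    def test_linear_chain_closure(self):
        m = load_network(LINEAR_CHAIN)
        sys_ = decompose(m, [full_emu(m, "B")])
        assert sys_.n_emus == 2  # A{1,2}, B{1,2}
        assert sys_.input_emus == [emu("Ain", (1, 2))]

    def test_cleavage_closure_follows_atom_maps(self):
        doc = """
metabolites:
  - {id: Cin, carbons: 3, role: input}
  - {id: C, carbons: 3}
  - {id: A, carbons: 1}
  - {id: B, carbons: 2}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Cin#abc -> C#abc"}
  - {id: cut, equation: "C#abc -> A#a + B#bc"}
  - {id: oa, equation: "A#a -> Out"}
  - {id: ob, equation: "B#ab -> Out"}
"""
        m = load_network(doc)
        sys_ = decompose(m, [full_emu(m, "A"), full_emu(m, "B")])
        emus = {str(e) for lv in sys_.levels for e in lv.emus}
        # manual closure: A{1} <- C{1}, B{1,2} <- C{2,3}
        assert emus == {"A{1}", "B{1,2}", "C{1}", "C{2,3}"}

    def test_unreachable_target_raises(self, branch_model):
        with pytest.raises(NetworkError):
            decompose(branch_model, [emu("S", (1, 2, 3, 4))])

    def test_bundled_closure_is_finite_and_bounded(self, bundled_model):
        from chemoflux.mids import load_panel, panel_target_emus

        targets = panel_target_emus(bundled_model, load_panel())
        sys_ = decompose(bundled_model, targets)
        max_size = max(lv.size for lv in sys_.levels)
        assert max_size <= max(
            bundled_model.metabolites[t.met].n_carbons for t in targets
        )
        assert sys_.n_emus < 1000


class TestSimulate:
    def test_full_labeling_propagates(self):
        m = load_network(LINEAR_CHAIN)
        basis = build_flux_basis(m, fixed={"upt": 3.0})
        st_ = basis.realize([])
        sys_ = decompose(m, [full_emu(m, "B")])
        mids = simulate_mids(sys_, st_, {emu("Ain", (1, 2)): np.array([0.0, 0.0, 1.0])})
        np.testing.assert_allclose(mids[full_emu(m, "B")], [0, 0, 1], atol=1e-12)

    def test_unlabeled_input_stays_unlabeled(self, cycle_model):
        rng = np.random.default_rng(3)
        st_ = random_flux_state(cycle_model, rng)
        sys_ = decompose(cycle_model, [full_emu(cycle_model, x) for x in "BCDE"])
        tracer = {e: np.eye(e.size + 1)[0] for e in sys_.input_emus}
        mids = simulate_mids(sys_, st_, tracer)
        for mid in mids.values():
            np.testing.assert_allclose(mid[0], 1.0, atol=1e-10)

    def test_zero_influx_pool_raises_named_error(self):
        doc = """
metabolites:
  - {id: Ain, carbons: 1, role: input}
  - {id: A, carbons: 1}
  - {id: B, carbons: 1}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Ain#a -> A#a"}
  - {id: ab, equation: "A#a -> B#a", bidirectional: true}
  - {id: out, equation: "B#a -> Out"}
  - {id: outa, equation: "A#a -> Out"}
"""
        m = load_network(doc)
        basis = build_flux_basis(m, fixed={"upt": 2.0})
        st_ = basis.realize(np.ones(len(basis.free_net)))
        st_.net[m.reaction_index["ab"]] = 0.0  # cut B's only influx
        st_.net[m.reaction_index["out"]] = 0.0
        st_.net[m.reaction_index["outa"]] = 2.0
        sys_ = decompose(m, [full_emu(m, "B")])
        with pytest.raises(SimulationError, match="B"):
            simulate_mids(sys_, st_, {emu("Ain", (1,)): np.array([1.0, 0.0])})

    def test_infinite_exchange_equilibrates_pools(self):
        doc = """
metabolites:
  - {id: Ain, carbons: 2, role: input}
  - {id: A, carbons: 2}
  - {id: B, carbons: 2}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Ain#ab -> A#ab"}
  - {id: swap, equation: "A#ab -> B#ba", bidirectional: true}
  - {id: outa, equation: "A#ab -> Out"}
  - {id: outb, equation: "B#ab -> Out"}
"""
        m = load_network(doc)
        basis = build_flux_basis(m, fixed={"upt": 1.0})
        free = basis.free_net
        st_ = basis.realize(np.full(len(free), 0.5), [1e6])
        sys_ = decompose(m, [full_emu(m, "A"), full_emu(m, "B")])
        tracer = {emu("Ain", (1, 2)): np.array([0.2, 0.5, 0.3])}
        mids = simulate_mids(sys_, st_, tracer)
        np.testing.assert_allclose(
            mids[full_emu(m, "A")], mids[full_emu(m, "B")], atol=1e-5
        )


SYM_FEEDFORWARD = """
name: sym_ff
metabolites:
  - {id: Sin, carbons: 2, role: input}
  - {id: R, carbons: 2}
  - {id: E, carbons: 4, symmetric: true}
  - {id: F, carbons: 2}
  - {id: Out, carbons: 0, role: output}
reactions:
  - {id: upt, equation: "Sin#ab -> R#ab"}
  - {id: cond, equation: "R#ab + R#cd -> E#adcb"}
  - {id: cut, equation: "E#abcd -> F#ab + F#dc"}
  - {id: out_f, equation: "F#ab -> Out"}
"""


class TestScramblingMids:
    def test_downstream_mid_averages_the_two_orientations(self):
        """Without feedback through the symmetric pool, the simulated MID
        downstream of it equals the average over the two fixed orientations
        of the unscrambled model (molecule-level indistinguishability)."""
        rng = np.random.default_rng(5)
        tensors = {"Sin": random_input_tensor(rng, 2)}

        def simulate(doc):
            m = load_network(doc)
            st_ = random_flux_state(m, np.random.default_rng(8))
            sys_ = decompose(m, [emu("F", (1, 2))])
            return simulate_mids(
                sys_, st_, _input_mids_from_tensors(sys_, tensors)
            )[emu("F", (1, 2))]

        scrambled = simulate(SYM_FEEDFORWARD)
        plain = SYM_FEEDFORWARD.replace("symmetric: true", "symmetric: false")
        mirrored = plain.replace("E#abcd -> F#ab + F#dc", "E#dcba -> F#ab + F#dc")
        average = 0.5 * (simulate(plain) + simulate(mirrored))
        np.testing.assert_allclose(scrambled, average, atol=1e-10)


class TestOracleAgreement:
    @pytest.mark.parametrize("name", sorted(TOY_DOCS))
    def test_emu_equals_isotopomer_oracle(self, name):
        doc = TOY_DOCS[name]
        m = load_network(doc)
        rng = np.random.default_rng(hash(name) % 2**31)
        for _ in range(5):
            st_ = random_flux_state(m, rng)
            tensors = {
                mm.id: random_input_tensor(rng, mm.n_carbons)
                for mm in m.metabolites.values()
                if mm.role == "input"
            }
            targets = [
                full_emu(m, mm.id)
                for mm in m.metabolites.values()
                if mm.role == "balanced"
            ]
            sys_ = decompose(m, targets)
            sim = simulate_mids(sys_, st_, _input_mids_from_tensors(sys_, tensors))
            oracle = isotopomer_oracle(m, st_, tensors)
            for t in targets:
                np.testing.assert_allclose(
                    sim[t], oracle[t.met], atol=1e-9,
                    err_msg=f"{name}: {t.met}",
                )

    def test_single_reaction_network_maps_input_through(self):
        m = load_network(LINEAR_CHAIN)
        rng = np.random.default_rng(1)
        st_ = random_flux_state(m, rng)
        t = random_input_tensor(rng, 2)
        oracle = isotopomer_oracle(m, st_, {"Ain": t})
        np.testing.assert_allclose(oracle["A"], tensor_mid(t, (1, 2)), atol=1e-11)
        np.testing.assert_allclose(oracle["B"], tensor_mid(t, (1, 2)), atol=1e-11)


class TestInvariants:
    @pytest.mark.parametrize("name", ["cycle", "loop_sym"])
    def test_normalization_preserved_at_every_level(self, name):
        m = load_network(TOY_DOCS[name])
        rng = np.random.default_rng(17)
        st_ = random_flux_state(m, rng)
        targets = [
            full_emu(m, mm.id) for mm in m.metabolites.values() if mm.role == "balanced"
        ]
        sys_ = decompose(m, targets)
        tensors = {
            mm.id: random_input_tensor(rng, mm.n_carbons)
            for mm in m.metabolites.values()
            if mm.role == "input"
        }
        mids = simulate_mids(sys_, st_, _input_mids_from_tensors(sys_, tensors))
        for mid in mids.values():
            assert np.sum(mid) == pytest.approx(1.0, abs=1e-9)
            assert np.all(mid > -1e-12)

    def test_simulated_mids_affine_in_each_input_emu_mid(self, branch_model):
        """Holding fluxes and all other inputs fixed, every output MID entry
        responds affinely to one input EMU's MID."""
        m = branch_model
        rng = np.random.default_rng(23)
        st_ = random_flux_state(m, rng)
        sys_ = decompose(m, [full_emu(m, "A"), full_emu(m, "B")])
        base_tensor = random_input_tensor(rng, 3)
        base = {e: tensor_mid(base_tensor, e.atoms) for e in sys_.input_emus}
        target = next(e for e in sys_.input_emus if e.size == 3)

        def out(mid):
            tracer = dict(base)
            tracer[target] = mid
            res = simulate_mids(sys_, st_, tracer)
            return np.concatenate([res[full_emu(m, "A")], res[full_emu(m, "B")]])

        m0 = tensor_mid(random_input_tensor(rng, 3), (1, 2, 3))
        m1 = tensor_mid(random_input_tensor(rng, 3), (1, 2, 3))
        lam = 0.37
        np.testing.assert_allclose(
            out(lam * m0 + (1 - lam) * m1),
            lam * out(m0) + (1 - lam) * out(m1),
            atol=1e-10,
        )

    def test_exchange_does_not_move_net_balances(self, cycle_model):
        rng = np.random.default_rng(29)
        st_ = random_flux_state(cycle_model, rng)
        iso = cycle_model.reaction_index["iso"]
        before = st_.balance_residuals()
        st_.exchange[iso] += 500.0
        np.testing.assert_allclose(st_.balance_residuals(), before, atol=1e-9)
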