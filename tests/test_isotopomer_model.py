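"""Unit and property tests for the atom-transition isotopomer simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletflux.isotopomer_model import (
    ConvergenceError,
    FluxConfig,
    IsotopomerDistribution,
    build_beta_cell_network,
    condense,
    mid_from_isotopomers,
    propagate_sweeps,
    propagate_to_steady_state,
    symmetry_scramble,
    transform,
)


def dist(met, n, fractions):
    return IsotopomerDistribution.from_fractions(met, n, fractions)


def reaction(net, name):
    for amap, _flux in net.reactions:
        if amap.reaction == name:
            return amap
    raise KeyError(name)


@pytest.fixture(scope="module")
def network():
    return build_beta_cell_network(FluxConfig())


class TestAtomMaps:
    """Single-reaction outcomes traced by hand from the carbon maps."""

    @pytest.mark.parametrize(
        "rxn,sub,pattern,expected",
        [
            ("ME_PEPCK", ("malate", 4), "1100", {"110": 1.0}),  # TCA-derived pyruvate
            ("ME_PEPCK", ("malate", 4), "0111", {"011": 1.0}),  # scrambled PC backbone
            ("AKGDH_SCS", ("akg", 5), "00011", {"0011": 1.0}),
            ("PDH", ("pyruvate", 3), "111", {"11": 1.0}),
            ("PDH", ("pyruvate", 3), "100", {"00": 1.0}),  # C1 leaves as CO2
            ("LDH", ("pyruvate", 3), "110", {"110": 1.0}),
        ],
    )
    def test_unary_hand_traces(self, network, rxn, sub, pattern, expected):
        amap = reaction(network, rxn)
        out = transform(dist(sub[0], sub[1], {pattern: 1.0}), amap)
        nonzero = {p: v for p, v in out.fractions.items() if v > 0}
        assert nonzero == pytest.approx(expected)

    def test_pdh_entry_labels_glutamate_positions_4_5(self, network):
        """Acetyl-CoA carbons land on aKG C4/C5, the basis of the
        glutamate 00011 signature of PDH-routed glucose carbon."""
        cs = reaction(network, "CS_ACO_IDH")
        oaa = IsotopomerDistribution.unlabeled("oaa", 4)
        accoa = dist("acetyl_coa", 2, {"11": 1.0})
        out = condense(oaa, accoa, cs)
        assert out.fraction("00011") == pytest.approx(1.0)

    def test_condense_unlabeled_substrates(self, network):
        cs = reaction(network, "CS_ACO_IDH")
        out = condense(
            IsotopomerDistribution.unlabeled("oaa", 4),
            IsotopomerDistribution.unlabeled("acetyl_coa", 2),
            cs,
        )
        assert out.fraction("00000") == pytest.approx(1.0)

    def test_condense_oaa_1110_with_unlabeled_accoa(self, network):
        """Hand trace: OAA 1110 + AcCoA 00 -> aKG 01100 and labeled CO2."""
        cs = reaction(network, "CS_ACO_IDH")
        oaa = dist("oaa", 4, {"1110": 1.0})
        accoa = IsotopomerDistribution.unlabeled("acetyl_coa", 2)
        akg = condense(oaa, accoa, cs)
        assert akg.fraction("01100") == pytest.approx(1.0)
        co2 = cs.apply([oaa.vector, accoa.vector])["co2"]
        assert co2[1] == pytest.approx(1.0)

    def test_pc_adds_unlabeled_co2_as_oaa_c4(self, network):
        pc = reaction(network, "PC")
        out = transform(dist("pyruvate", 3, {"111": 1.0}), pc)
        assert out.fraction("1110") == pytest.approx(1.0)

    def test_pc_with_labeled_co2_pool(self):
        net = build_beta_cell_network(FluxConfig(co2_enrichment=0.25))
        pc = reaction(net, "PC")
        pyr = dist("pyruvate", 3, {"111": 1.0})
        out = pc.apply([pyr.vector], co2_enrichment=0.25)["oaa"]
        oaa = IsotopomerDistribution("oaa", 4, out)
        assert oaa.fraction("1111") == pytest.approx(0.25)
        assert oaa.fraction("1110") == pytest.approx(0.75)

    def test_condense_mixture_product_is_pairwise_sum(self, network):
        cs = reaction(network, "CS_ACO_IDH")
        oaa = dist("oaa", 4, {"0000": 0.6, "1110": 0.4})
        accoa = dist("acetyl_coa", 2, {"00": 0.3, "11": 0.7})
        akg = condense(oaa, accoa, cs)
        assert akg.fraction("00011") == pytest.approx(0.6 * 0.7)
        assert akg.fraction("01100") == pytest.approx(0.4 * 0.3)
        assert akg.fraction("01111") == pytest.approx(0.4 * 0.7)
        assert akg.vector.sum() == pytest.approx(1.0)

    def test_no_pc_flux_removes_pc_production(self):
        net = build_beta_cell_network(FluxConfig(v_PC=0.0, v_PDH=1.0))
        oaa_producers = [m.reaction for m, f in net.reactions
                        if f > 0 and any(p == "oaa" for p, _ in m.products)]
        assert "PC" not in oaa_producers


class TestSymmetryScramble:
    def test_half_half_reversal(self):
        out = symmetry_scramble(dist("succinate", 4, {"1100": 1.0}))
        assert out.fractions["1100"] == pytest.approx(0.5)
        assert out.fractions["0011"] == pytest.approx(0.5)

    def test_palindrome_unchanged(self):
        out = symmetry_scramble(dist("succinate", 4, {"0110": 1.0}))
        assert out.fraction("0110") == pytest.approx(1.0)

    def test_uniform_fixed_point(self):
        d = IsotopomerDistribution("succinate", 4, np.full(16, 1 / 16))
        assert np.allclose(symmetry_scramble(d).vector, d.vector)

    def test_wrong_carbon_count_rejected(self):
        with pytest.raises(ValueError):
            symmetry_scramble(dist("pyruvate", 3, {"110": 1.0}))

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=16, max_size=16))
    def test_involution(self, weights):
        vec = np.array(weights)
        vec /= vec.sum()
        d = IsotopomerDistribution("succinate", 4, vec)
        once = symmetry_scramble(d)
        twice = symmetry_scramble(once)
        assert np.allclose(once.vector, twice.vector, atol=1e-12)


class TestMid:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ({"111": 1.0}, (0, 0, 0, 1)),
            ({"110": 0.5, "011": 0.5}, (0, 0, 1, 0)),
        ],
    )
    def test_examples(self, fractions, expected):
        mid = mid_from_isotopomers(dist("lactate", 3, fractions))
        assert mid == pytest.approx(np.array(expected))

    def test_uniform_is_binomial_counts(self):
        d = IsotopomerDistribution("lactate", 3, np.full(8, 1 / 8))
        assert mid_from_isotopomers(d) == pytest.approx(
            np.array([1 / 8, 3 / 8, 3 / 8, 1 / 8])
        )

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        st.integers(3, 4),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_popcount_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        vec = rng.dirichlet(np.ones(2**n))
        d = IsotopomerDistribution("met", n, vec)
        mid = mid_from_isotopomers(d)
        # independent brute-force oracle over explicit pattern strings
        expected = np.zeros(n + 1)
        for pattern, frac in d.fractions.items():
            expected[pattern.count("1")] += frac
        assert mid == pytest.approx(expected, abs=1e-12)
        assert mid.sum() == pytest.approx(1.0)


class TestFluxConfig:
    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            FluxConfig(v_PC=-0.1)

    def test_enrichment_bounds(self):
        with pytest.raises(ValueError):
            FluxConfig(tracer_enrichment=1.5)

    def test_glycolysis_autobalanced(self):
        cfg = FluxConfig(v_PDH=0.7, v_PC=0.3, v_LDH=0.5, v_ALT=0.1, v_ME=0.2)
        assert cfg.v_glycolysis == pytest.approx(0.7 + 0.3 + 0.5 + 0.1 - 0.2)

    def test_unbalanced_explicit_glycolysis_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            FluxConfig(v_glycolysis=5.0)

    def test_pc_fraction(self):
        assert FluxConfig(v_PDH=0.8, v_PC=0.2).f_PC == pytest.approx(0.2)
        cfg = FluxConfig().with_pc_fraction(0.35)
        assert cfg.f_PC == pytest.approx(0.35)
        assert cfg.v_PC + cfg.v_PDH == pytest.approx(1.0)


class TestSteadyState:
    def test_no_tracer_everything_unlabeled(self):
        net = build_beta_cell_network(FluxConfig(tracer_enrichment=0.0))
        ss = propagate_to_steady_state(net)
        for d in ss.values():
            assert d.vector[0] == pytest.approx(1.0)

    def test_distributions_sum_to_one(self):
        ss = propagate_to_steady_state(build_beta_cell_network(FluxConfig()))
        for d in ss.values():
            d.validate()

    def test_pdh_signature_first_pass(self):
        """With PC and the malate return shut off and a pure tracer, the only
        labeled glutamate isotopomer after one propagation pass is 00011."""
        cfg = FluxConfig(v_PC=0.0, v_ME=0.0, tracer_enrichment=1.0)
        one = propagate_sweeps(build_beta_cell_network(cfg), 1)
        labeled = {
            p: v
            for p, v in one["glutamate"].fractions.items()
            if v > 0 and p != "00000"
        }
        assert set(labeled) == {"00011"}
        assert labeled["00011"] > 0

    def test_pc_raises_lactate_011(self):
        ss = propagate_to_steady_state(
            build_beta_cell_network(FluxConfig().with_pc_fraction(0.3))
        )
        assert ss["lactate"].fraction("011") > 0

    def test_lactate_011_not_forced_to_zero_without_pc(self):
        """Multi-turn PDH-only flux still produces a little 011 through the
        malate return; the simulator quantifies rather than zeroes it."""
        ss = propagate_to_steady_state(
            build_beta_cell_network(FluxConfig(v_PC=0.0, v_PDH=1.0))
        )
        assert 0 < ss["lactate"].fraction("011") < 0.02

    def test_lactate_011_nondecreasing_in_pc_fraction(self):
        base = FluxConfig()
        values = []
        for f_pc in np.arange(0.0, 0.51, 0.1):
            net = build_beta_cell_network(base.with_pc_fraction(float(f_pc)))
            values.append(
                propagate_to_steady_state(net)["lactate"].fraction("011")
            )
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_lactate_110_dominates_011(self):
        """Oxidative TCA-derived lactate (110) exceeds the PC-derived
        reductive signature (011) under default fluxes."""
        ss = propagate_to_steady_state(build_beta_cell_network(FluxConfig()))
        assert ss["lactate"].fraction("110") > ss["lactate"].fraction("011")

    def test_glutamate_00011_most_abundant_labeled(self):
        ss = propagate_to_steady_state(build_beta_cell_network(FluxConfig()))
        glu = ss["glutamate"].fractions
        labeled = {p: v for p, v in glu.items() if p != "00000"}
        assert max(labeled, key=labeled.get) == "00011"

    def test_lactate_equals_pyruvate(self):
        ss = propagate_to_steady_state(build_beta_cell_network(FluxConfig()))
        assert np.allclose(ss["lactate"].vector, ss["pyruvate"].vector)

    def test_g3p_is_glycolytic_two_point_mixture(self):
        cfg = FluxConfig(tracer_enrichment=0.37)
        ss = propagate_to_steady_state(build_beta_cell_network(cfg))
        assert ss["g3p"].fraction("111") == pytest.approx(0.37)
        assert ss["g3p"].fraction("000") == pytest.approx(0.63)

    def test_nonconvergence_reports_residual(self):
        net = build_beta_cell_network(FluxConfig())
        with pytest.raises(ConvergenceError) as err:
            propagate_to_steady_state(net, tol=1e-10, max_iter=2)
        assert err.value.residual > 0

    def test_accelerated_solution_matches_plain_iteration(self):
        from isletflux.isotopomer_model import _init_pools, _sweep

        net = build_beta_cell_network(FluxConfig())
        dists, order = _init_pools(net)
        pools = {**net.fixed_distributions, **dists}
        for _ in range(600):
            _sweep(net, pools, order)
        ss = propagate_to_steady_state(net, tol=1e-12)
        for name, _n in order:
            assert np.allclose(ss[name].vector, pools[name], atol=1e-9)
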