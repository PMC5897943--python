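"""Reaction-network validation, steady-state solving, and mutation effects."""

from __future__ import annotations

import copy

import pytest

from immunotree import (
    MutationEffect,
    MutationPerturbation,
    NetworkSpec,
    apply_perturbations,
    michaelis_menten_rate,
    predict_profile,
    simulate_to_steady_state,
)
from immunotree.network import (
    Modifier,
    NetworkSchemaError,
    Reaction,
    Species,
    load_network,
)


def _mut(gene, effect, magnitude=None):
    return MutationPerturbation(gene, MutationEffect(effect), magnitude)


def _pdl1_change(network, baseline, mutations):
    result = predict_profile(network, mutations, baseline=baseline)
    assert result.converged
    return result.percent_changes["PDL1"]


class TestMichaelisMentenRate:
    @pytest.mark.parametrize(
        "substrate, vmax, km, expected",
        [
            (1.0, 4.0, 1.0, 2.0),   # half saturation at S = Km
            (0.0, 4.0, 1.0, 0.0),
            (3.0, 2.0, 1.0, 1.5),
        ],
    )
    def test_examples(self, substrate, vmax, km, expected):
        assert michaelis_menten_rate(substrate, vmax, km) == pytest.approx(
            expected
        )

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError, match="substrate"):
            michaelis_menten_rate(-0.1, 1.0, 1.0)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError, match="Km"):
            michaelis_menten_rate(1.0, 1.0, 0.0)

    def test_saturates_below_vmax(self):
        assert michaelis_menten_rate(1e9, 2.0, 1.0) < 2.0


class TestNetworkSchema:
    def test_bundled_network_is_valid(self, pdl1_network):
        assert "PDL1" in pdl1_network.outputs
        assert len(pdl1_network.outputs) == 24
        assert len(pdl1_network.species) >= 20

    def test_zero_km_rejected(self):
        with pytest.raises(NetworkSchemaError, match="Km"):
            NetworkSpec(
                species=[Species("A"), Species("PDL1")],
                reactions=[
                    Reaction(
                        id="r1",
                        kind="michaelis_menten",
                        products=["PDL1"],
                        substrates=["A"],
                        parameters={"Vmax": 1.0, "Km": 0.0},
                    )
                ],
                outputs=["PDL1"],
            )

    def test_undeclared_species_rejected(self):
        with pytest.raises(NetworkSchemaError, match="GHOST"):
            NetworkSpec(
                species=[Species("PDL1")],
                reactions=[
                    Reaction(
                        id="r1",
                        kind="mass_action",
                        products=["PDL1"],
                        substrates=["GHOST"],
                        parameters={"k": 1.0},
                    )
                ],
                outputs=["PDL1"],
            )

    def test_degenerate_network_with_no_reactions_is_valid(self):
        spec = NetworkSpec(
            species=[Species("PDL1", baseline_synthesis_rate=1.0)],
            reactions=[],
            outputs=["PDL1"],
        )
        assert spec.species_names() == ["PDL1"]

    def test_negative_rate_parameter_rejected(self):
        with pytest.raises(NetworkSchemaError, match="Vmax"):
            NetworkSpec(
                species=[Species("PDL1")],
                reactions=[
                    Reaction(
                        id="r1",
                        kind="michaelis_menten",
                        products=["PDL1"],
                        parameters={"Vmax": -1.0, "Km": 1.0},
                    )
                ],
                outputs=["PDL1"],
            )

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "tiny.yaml"
        path.write_text(
            """
name: tiny
species:
  - {name: PDL1, baseline_synthesis_rate: 1.0, degradation_rate: 0.5}
reactions: []
outputs: [PDL1]
"""
        )
        spec = load_network(path)
        assert spec.name == "tiny"
        assert spec.species[0].degradation_rate == 0.5


class TestSteadyState:
    def test_single_species_closed_form(self):
        # dX/dt = k - d X  =>  X* = k/d = 2.0
        spec = NetworkSpec(
            species=[
                Species("PDL1", baseline_synthesis_rate=1.0,
                        degradation_rate=0.5)
            ],
            reactions=[],
            outputs=["PDL1"],
        )
        result = simulate_to_steady_state(spec)
        assert result.converged
        assert result.state["PDL1"] == pytest.approx(2.0, abs=1e-6)

    def test_zero_synthesis_gives_zero_state(self):
        spec = NetworkSpec(
            species=[
                Species("PDL1", initial_concentration=3.0),
                Species("A", initial_concentration=1.0),
            ],
            reactions=[],
            outputs=["PDL1"],
        )
        result = simulate_to_steady_state(spec)
        assert result.converged
        assert all(abs(v) < 1e-6 for v in result.state.values())

    def test_bundled_network_converges(self, pdl1_baseline):
        assert pdl1_baseline.converged
        assert pdl1_baseline.residual < 1e-9
        assert all(v >= 0 for v in pdl1_baseline.state.values())

    def test_steady_state_is_tolerance_robust(self, pdl1_network, pdl1_baseline):
        tight = simulate_to_steady_state(
            pdl1_network, tol_abs=5e-10, tol_rel=5e-9
        )
        for name, value in pdl1_baseline.state.items():
            scale = max(abs(value), 1e-9)
            assert abs(tight.state[name] - value) / scale < 1e-4


class TestPerturbations:
    def test_empty_mutation_list_is_identity(self, pdl1_network):
        perturbed = apply_perturbations(pdl1_network, [])
        assert perturbed == pdl1_network

    def test_input_spec_never_modified(self, pdl1_network):
        snapshot = copy.deepcopy(pdl1_network)
        apply_perturbations(
            pdl1_network,
            [_mut("KRAS", "oncogene_gof"), _mut("TP53", "tsg_lof")],
        )
        assert pdl1_network == snapshot

    def test_unknown_gene_lists_valid_nodes(self, pdl1_network):
        with pytest.raises(KeyError, match="KRAS"):
            apply_perturbations(pdl1_network, [_mut("NOTAGENE", "tsg_lof")])

    def test_gof_scales_driven_reaction_rate(self, pdl1_network):
        perturbed = apply_perturbations(
            pdl1_network, [_mut("KRAS", "oncogene_gof", 5.0)]
        )
        original = {r.id: r for r in pdl1_network.reactions}
        changed = {r.id: r for r in perturbed.reactions}
        assert changed["act_braf"].parameters["Vmax"] == pytest.approx(
            5.0 * original["act_braf"].parameters["Vmax"]
        )
        # reactions KRAS does not drive are untouched
        assert changed["act_mek"].parameters == original["act_mek"].parameters

    def test_lof_relaxes_inhibition_constant(self, pdl1_network):
        perturbed = apply_perturbations(
            pdl1_network, [_mut("TP53", "tsg_lof", 10.0)]
        )
        original = next(
            r for r in pdl1_network.reactions if r.id == "txn_pdl1_ap1"
        )
        changed = next(
            r for r in perturbed.reactions if r.id == "txn_pdl1_ap1"
        )
        assert changed.inhibitors[0].constant == pytest.approx(
            10.0 * original.inhibitors[0].constant
        )

    def test_amplification_and_deletion_act_on_synthesis(self, pdl1_network):
        amplified = apply_perturbations(
            pdl1_network, [_mut("EGFR", "amplification", 5.0)]
        )
        deleted = apply_perturbations(pdl1_network, [_mut("EGFR", "deletion")])
        base = next(s for s in pdl1_network.species if s.name == "EGFR")
        assert next(
            s for s in amplified.species if s.name == "EGFR"
        ).baseline_synthesis_rate == pytest.approx(
            5.0 * base.baseline_synthesis_rate
        )
        assert next(
            s for s in deleted.species if s.name == "EGFR"
        ).baseline_synthesis_rate == 0.0

    def test_nonpositive_magnitude_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _mut("KRAS", "oncogene_gof", -2.0).resolved_magnitude()


class TestProfilePrediction:
    def test_zero_perturbation_identity(self, pdl1_network, pdl1_baseline):
        result = predict_profile(pdl1_network, [], baseline=pdl1_baseline)
        assert result.converged
        for molecule, change in result.percent_changes.items():
            assert abs(change) < 0.01, molecule

    def test_kras_gain_raises_pdl1(self, pdl1_network, pdl1_baseline):
        change = _pdl1_change(
            pdl1_network, pdl1_baseline, [_mut("KRAS", "oncogene_gof")]
        )
        assert change > 0

    def test_kras_comutation_ordering(self, pdl1_network, pdl1_baseline):
        """PD-L1 ordering across KRAS co-mutation subgroups: KP > K > KL > KC."""
        kras = [_mut("KRAS", "oncogene_gof")]
        kp = _pdl1_change(
            pdl1_network, pdl1_baseline, kras + [_mut("TP53", "tsg_lof")]
        )
        k = _pdl1_change(pdl1_network, pdl1_baseline, kras)
        kl = _pdl1_change(
            pdl1_network,
            pdl1_baseline,
            kras + [_mut("STK11", "tsg_lof"), _mut("KEAP1", "tsg_lof")],
        )
        kc = _pdl1_change(
            pdl1_network, pdl1_baseline, kras + [_mut("CDKN2A", "tsg_lof")]
        )
        assert kp > k > kl > kc

    def test_monotone_dose_response_in_gof_magnitude(
        self, pdl1_network, pdl1_baseline
    ):
        changes = [
            _pdl1_change(
                pdl1_network,
                pdl1_baseline,
                [_mut("KRAS", "oncogene_gof", magnitude)],
            )
            for magnitude in (1.0, 2.0, 5.0, 10.0)
        ]
        assert changes == sorted(changes)
        assert changes[0] == pytest.approx(0.0, abs=0.01)  # magnitude 1 = wild type
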