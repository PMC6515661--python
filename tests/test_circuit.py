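"""Parameter validation and reaction-network structure."""

from dataclasses import replace

import numpy as np
import pytest

from caacircuit import (
    CircuitParameters,
    ParameterError,
    build_multisite_network,
    build_network,
    default_parameters,
)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "changes, field",
        [
            (dict(copies_A=0), "copies_A"),
            (dict(copies_B=-1), "copies_B"),
            (dict(operator_sites=0), "operator_sites"),
            (dict(delta_m=-0.1), "delta_m"),
            (dict(alpha_basal=100.0), "alpha"),  # breaks basal <= active
            (dict(alpha_repressed=7.0, repression_mode="weak"), "alpha"),
            (dict(repression_mode="medium"), "repression_mode"),
            (dict(alpha_repressed=1.0), "strong"),  # strong demands zero leak
            (dict(k_rep_off=2.0), "strong"),  # strong demands slow repressor exit
            (dict(repression_mode="weak"), "weak"),  # weak demands a leak
        ],
    )
    def test_invalid_parameters_name_the_offender(self, changes, field):
        base = default_parameters("strong").to_dict()
        base.update(changes)
        with pytest.raises(ParameterError, match=field):
            CircuitParameters.from_dict(base)

    def test_unknown_field_rejected(self):
        with pytest.raises(ParameterError, match="nonsense"):
            CircuitParameters.from_dict({"nonsense": 1.0})

    @pytest.mark.parametrize("mode", ["strong", "weak"])
    def test_defaults_satisfy_invariants(self, mode):
        p = default_parameters(mode)
        assert p.alpha_repressed <= p.alpha_basal <= p.alpha_active
        # bursting regime: slow promoter switching relative to transcription
        assert p.k_act_off < p.alpha_active / 10
        assert p.k_rep_off < p.alpha_active / 10
        if mode == "strong":
            assert p.alpha_repressed == 0
            assert p.k_rep_off <= p.k_act_off
        else:
            assert p.alpha_repressed > 0
            assert p.K_rep > default_parameters("strong").K_rep


class TestNetworkStructure:
    def test_species_and_reaction_counts(self, strong_params, weak_params):
        # strong (alpha_repressed = 0): the two repressed-transcription
        # channels are dropped, leaving 9 reactions per side
        net = build_network(strong_params)
        assert len(net.species) == 10
        assert len(net.reactions) == 18
        # weak mode keeps all 10 channels per side
        assert len(build_network(weak_params).reactions) == 20

    def test_promoter_conservation_by_stoichiometry(self, strong_network):
        S = strong_network.stoichiometry_matrix()
        for side in "AB":
            idx = [strong_network.species_index(f"promoter_{st}_{side}") for st in ("free", "act", "rep")]
            assert np.all(S[:, idx].sum(axis=1) == 0)

    def test_copies_set_initial_promoter_totals(self, strong_params):
        net = build_network(strong_params.with_copies(2, 5))
        x0 = net.initial_state()
        assert x0[net.species_index("promoter_free_A")] == 2
        assert x0[net.species_index("promoter_free_B")] == 5
        assert net.check_conservation(x0)

    def test_zero_transcription_rates_give_zero_propensities(self, strong_params):
        d = strong_params.to_dict()
        d.update(alpha_active=0.0, alpha_basal=0.0, alpha_repressed=0.0)
        net = build_network(CircuitParameters.from_dict(d))
        assert not any("transcribe" in r.name for r in net.reactions)
        x = net.initial_state()
        x[net.species_index("protein_A")] = 500
        a = net.propensities(x)
        mrna_idx = [net.species_index(f"mrna_{s}") for s in "AB"]
        producing = [q for q, r in enumerate(net.reactions) if any(r.stoichiometry[i] > 0 for i in mrna_idx)]
        assert producing == []
        assert np.all(a >= 0)

    def test_symmetric_network_is_label_swap_invariant(self, strong_network):
        def canon(reaction, swap):
            name = reaction.name
            st = list(reaction.stoichiometry)
            if swap:
                name = name.translate(str.maketrans("AB", "BA"))
                st = st[5:] + st[:5]
            return name[:-2] + name[-1], tuple(st), reaction.kind, reaction.rate

        plain = sorted(canon(r, False) for r in strong_network.reactions)
        swapped = sorted(canon(r, True) for r in strong_network.reactions)
        assert plain == swapped

    def test_dimeric_binding_propensity(self, strong_network, strong_params):
        x = strong_network.initial_state()
        ip = strong_network.species_index("protein_A")
        bind = next(r for r in strong_network.reactions if r.name == "act_bind_A")
        x[ip] = 10
        assert bind.propensity(x) == pytest.approx(strong_params.k_act_on * 1 * 45)
        x[ip] = 1  # a single monomer cannot form a dimer
        assert bind.propensity(x) == 0.0


class TestMultisiteNetwork:
    def test_tracks_only_mrna_and_protein(self, strong_params):
        net = build_multisite_network(replace(strong_params, operator_sites=7))
        assert net.species == ("mrna_A", "protein_A", "mrna_B", "protein_B")
        assert len(net.reactions) == 8

    def test_transcription_propensity_matches_occupancy_model(self, strong_params):
        from caacircuit.promoter import default_activity, expected_activity

        p = replace(strong_params, operator_sites=3)
        net = build_multisite_network(p)
        x = np.array([0, 40, 0, 25], dtype=np.int64)
        tr_A = next(r for r in net.reactions if r.name == "transcribe_A")
        act = 40 * 39 / 2
        rep = 25 * 24 / 2
        expected = expected_activity(
            3,
            act,
            rep,
            p.K_act,
            p.K_rep,
            default_activity(p.alpha_active, p.alpha_basal, p.alpha_repressed, p.repression_dominance),
        )
        assert tr_A.propensity(x) == pytest.approx(expected, rel=1e-10)
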