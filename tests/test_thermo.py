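import math

import numpy as np
import pytest

from maxentflux.thermo import (
    Conditions,
    PseudoisomerGroup,
    PseudoisomerSpecies,
    R,
    ThermoTable,
    adjust_species,
    mode_reaction_properties,
    phase_average,
    proton_balance,
    pseudoisomer_average,
)

from ._oracles import alberty_group_potential


@pytest.fixture
def cond():
    return Conditions(T=310.15, pH=7.0, ionic_strength=0.25)


@pytest.fixture
def table():
    return ThermoTable.curated()


class TestAdjustSpecies:
    def test_neutral_species_at_reference_is_unchanged(self):
        sp = PseudoisomerSpecies(dfG0=-100.0, dfH0=-200.0, charge=0, nH=0)
        cond = Conditions(T=310.15, pH=7.0, ionic_strength=0.0)
        mu, h = adjust_species(sp, cond, 1.0)
        assert mu == pytest.approx(-100.0)
        assert h == pytest.approx(-200.0)

    def test_concentration_term_vanishes_at_reference(self, cond):
        sp = PseudoisomerSpecies(dfG0=-50.0, dfH0=-60.0, charge=-1, nH=1)
        mu_ref, _ = adjust_species(sp, cond, 1.0)
        mu_dil, _ = adjust_species(sp, cond, 0.01)
        assert mu_dil - mu_ref == pytest.approx(
            R / 1000 * cond.T * math.log(0.01)
        )

    def test_ph_term_scales_with_hydrogen_count(self, cond):
        base = dict(dfG0=0.0, dfH0=0.0, charge=0)
        mu1, _ = adjust_species(PseudoisomerSpecies(**base, nH=1), cond, 1.0)
        mu2, _ = adjust_species(PseudoisomerSpecies(**base, nH=2), cond, 1.0)
        # each proton adds RT ln10 pH, minus its Debye-Hueckel share
        assert mu2 - mu1 == pytest.approx(mu1 - 0.0)

    def test_nonpositive_concentration_rejected(self, cond):
        sp = PseudoisomerSpecies(dfG0=0.0, dfH0=0.0)
        with pytest.raises(ValueError):
            adjust_species(sp, cond, 0.0)


class TestPseudoisomerAverage:
    def test_single_species_identity(self, cond):
        sp = PseudoisomerSpecies(dfG0=-10.0, dfH0=-20.0, charge=-1, nH=1)
        group = PseudoisomerGroup("x", [sp])
        props = pseudoisomer_average(group, cond, 1.0)
        mu, h = adjust_species(sp, cond, 1.0)
        assert props.g == pytest.approx(mu)
        assert props.h == pytest.approx(h)
        assert props.weights[0] == pytest.approx(1.0)

    def test_equal_potentials_split_evenly(self, cond):
        sp = PseudoisomerSpecies(dfG0=-10.0, dfH0=-5.0)
        group = PseudoisomerGroup("x", [sp, sp])
        props = pseudoisomer_average(group, cond, 1.0)
        assert np.allclose(props.weights, [0.5, 0.5])

    def test_weights_normalize_and_shift_invariant(self, cond):
        species = [
            PseudoisomerSpecies(dfG0=g, dfH0=0.0, charge=z, nH=n)
            for g, z, n in [(-10, 0, 0), (-12, -1, 1), (-8, -2, 2)]
        ]
        w1 = pseudoisomer_average(PseudoisomerGroup("x", species), cond, 1.0).weights
        shifted = [
            PseudoisomerSpecies(dfG0=sp.dfG0 + 17.3, dfH0=0.0, charge=sp.charge, nH=sp.nH)
            for sp in species
        ]
        w2 = pseudoisomer_average(PseudoisomerGroup("x", shifted), cond, 1.0).weights
        assert abs(w1.sum() - 1.0) < 1e-12
        assert np.allclose(w1, w2, atol=1e-12)

    def test_phosphate_group_at_ph7(self, cond, table):
        props = table.adjusted("po4", cond)
        group = table.group("po4")
        names_by_weight = sorted(
            zip(props.weights, [sp.nH for sp in group.species]), reverse=True
        )
        # dominant pair is H2PO4- / HPO4-- (nH 2 and 1)
        assert {names_by_weight[0][1], names_by_weight[1][1]} == {1.0, 2.0}
        assert names_by_weight[0][0] + names_by_weight[1][0] > 0.99
        assert -2.0 < props.mean_charge < -1.0

    def test_group_potential_matches_independent_transcription(self, cond, table):
        group = table.group("po4")
        oracle = alberty_group_potential(
            [(sp.dfG0, sp.charge, sp.nH) for sp in group.species],
            cond.T,
            cond.pH,
            cond.ionic_strength,
        )
        props = table.adjusted("po4", cond)
        assert props.g == pytest.approx(oracle, abs=0.5)


class TestPhaseAverage:
    def test_endpoints_and_mixture(self, cond, table):
        group = table.group("h2o")
        aq = [sp for sp in group.species if sp.phase != "gas"]
        gas = [sp for sp in group.species if sp.phase == "gas"]
        liq = pseudoisomer_average(group, cond, 1.0, species=aq)
        vap = pseudoisomer_average(group, cond, 1.0, species=gas)
        assert phase_average(liq, vap, 0.0).g == pytest.approx(liq.g)
        assert phase_average(liq, vap, 1.0).g == pytest.approx(vap.g)
        mixed = phase_average(liq, vap, 0.04)
        assert mixed.g == pytest.approx(0.96 * liq.g + 0.04 * vap.g)
        assert mixed.h == pytest.approx(0.96 * liq.h + 0.04 * vap.h)

    def test_fraction_out_of_range(self, cond, table):
        group = table.group("h2o")
        props = pseudoisomer_average(group, cond, 1.0)
        with pytest.raises(ValueError):
            phase_average(props, props, 1.5)


class TestProtonBalance:
    def test_single_anion_product(self):
        assert proton_balance({"ac.Ext": 1.0}, {"ac.Ext": -1.0}) == pytest.approx(1.0)

    def test_all_neutral(self):
        charges = {"glc.Ext": 0.0, "h2o.Ext": 0.0}
        stoich = {"glc.Ext": -1.0, "h2o.Ext": 6.0}
        assert proton_balance(stoich, charges) == pytest.approx(0.0)

    def test_three_species_hand_audit(self):
        # consume NH4+-dominant ammonia (z=+0.9), produce acetate (z=-1),
        # produce neutral biomass: net charge = (-1)(+0.9) + (+1)(-1) = -1.9
        stoich = {"nh3.Ext": -1.0, "ac.Ext": 1.0, "biomass": 1.0}
        charges = {"nh3.Ext": 0.9, "ac.Ext": -1.0, "biomass": 0.0}
        assert proton_balance(stoich, charges) == pytest.approx(1.9)

    def test_missing_charge_data_raises(self):
        with pytest.raises(KeyError, match="mystery"):
            proton_balance({"mystery": 1.0}, {})


class TestModeReactionProperties:
    def test_identity_reaction_is_zero(self, cond, table):
        mt = mode_reaction_properties({"glc.Ext": -1.0, "glc": 1.0}, table, cond)
        assert mt.dg == pytest.approx(0.0, abs=1e-9)
        assert mt.dh == pytest.approx(0.0, abs=1e-9)
        assert mt.ds == pytest.approx(0.0, abs=1e-9)

    def test_gibbs_relation_and_affinity(self, cond, table):
        stoich = {"glc.Ext": -1.0, "o2.Ext": -6.0, "co2.Ext": 6.0, "h2o.Ext": 6.0}
        gf = {"o2": 1.0, "co2": 1.0, "h2o": 0.04}
        mt = mode_reaction_properties(stoich, table, cond, gf)
        assert mt.dg == pytest.approx(mt.dh - cond.T * mt.ds, rel=1e-12)
        assert mt.affinity == -mt.dg

    def test_linearity_in_stoichiometry(self, cond, table):
        stoich = {"glc.Ext": -1.0, "o2.Ext": -6.0, "co2.Ext": 6.0, "h2o.Ext": 6.0}
        mt1 = mode_reaction_properties(stoich, table, cond)
        mt2 = mode_reaction_properties(
            {k: 2 * v for k, v in stoich.items()}, table, cond
        )
        assert mt2.dg == pytest.approx(2 * mt1.dg)
        assert mt2.dh == pytest.approx(2 * mt1.dh)
        assert mt2.ds == pytest.approx(2 * mt1.ds)

    def test_aerobic_growth_is_spontaneous_with_positive_entropy(self, cond, table):
        # growth-like external equation: glucose + O2 + ammonia ->
        # biomass + CO2 + water, per mole glucose
        cond_growth = Conditions(
            T=310.15,
            pH=7.0,
            ionic_strength=0.25,
            concentrations={"h2o": 55.34, "glc": 0.00555},
        )
        stoich = {
            "glc.Ext": -1.0,
            "o2.Ext": -2.9,
            "nh3.Ext": -0.75,
            "biomass": 2.9,
            "co2.Ext": 3.1,
            "h2o.Ext": 4.0,
        }
        gf = {"o2": 1.0, "co2": 1.0, "h2o": 0.04}
        mt = mode_reaction_properties(stoich, table, cond_growth, gf)
        assert mt.dg < 0
        assert mt.ds > 0
        assert mt.dh < 0  # exothermic

    def test_proton_contributes_count_not_energy(self, cond, table):
        base = {"glc.Ext": -1.0, "co2.Ext": 6.0}
        with_h = dict(base, **{"h.Ext": 2.5})
        mt0 = mode_reaction_properties(base, table, cond)
        mt1 = mode_reaction_properties(with_h, table, cond)
        assert mt1.dg == pytest.approx(mt0.dg)
        assert mt1.protons_balanced == pytest.approx(2.5)

    def test_missing_species_raises(self, cond, table):
        with pytest.raises(KeyError, match="unobtainium"):
            mode_reaction_properties({"unobtainium": 1.0}, table, cond)
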