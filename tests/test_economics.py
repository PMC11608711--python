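"""Costing: dosing arithmetic, SAE sums, QALY accrual, incremental analysis."""

import numpy as np
import pytest

from psmcea import RunConfig
from psmcea.economics import (
    Patient, RegimenComponent, atezolizumab_cap_cycles, cost_components,
    drug_cost_per_cycle, efficiency_frontier, icer_table, pairwise_icers,
    qaly_trace, regimen_components, sae_cost, SAE_PROFILES,
)
from psmcea.psm import compute_occupancy


@pytest.fixture()
def patient():
    return Patient()


def _flat_occupancy(n, pfs=1.0, pd=0.0):
    os_v = np.full(n, pfs + pd)
    pfs_v = np.full(n, pfs)
    os_v[0] = pfs_v[0] = 1.0
    return compute_occupancy(os_v, pfs_v)


class TestDosing:
    def test_bevacizumab_per_kg(self, patient, values):
        comp = next(c for c in regimen_components("BC", RunConfig())
                    if c.drug == "bevacizumab")
        # 15 mg/kg x 77.5 kg = 1162.5 mg at $72.5 per 10 mg pack
        assert comp.resolved_dose_mg(patient) == pytest.approx(1162.5)
        assert drug_cost_per_cycle(comp, patient, values) == pytest.approx(8428.125)

    def test_atezolizumab_flat(self, patient, values):
        comp = next(c for c in regimen_components("ABC", RunConfig())
                    if c.drug == "atezolizumab")
        # 1200 mg at $85.8 per 10 mg
        assert drug_cost_per_cycle(comp, patient, values) == pytest.approx(10296.0)

    def test_pembrolizumab_flat(self, patient, values):
        comp = next(c for c in regimen_components("PBC", RunConfig())
                    if c.drug == "pembrolizumab")
        # 200 mg at $56.7 per mg
        assert drug_cost_per_cycle(comp, patient, values) == pytest.approx(11340.0)

    def test_chemotherapy_per_m2(self, patient, values):
        comps = {c.drug: c for c in regimen_components("BC", RunConfig())}
        # paclitaxel 175 mg/m2 x 1.86 m2 = 325.5 mg at $0.1/mg
        assert drug_cost_per_cycle(comps["paclitaxel"], patient, values) \
            == pytest.approx(32.55)
        # cisplatin 75 mg/m2 x 1.86 m2 = 139.5 mg at $3.7 per 10 mg
        assert drug_cost_per_cycle(comps["cisplatin"], patient, values) \
            == pytest.approx(51.615)
        assert comps["paclitaxel"].max_cycles == 6
        assert comps["cisplatin"].max_cycles == 6

    def test_atezolizumab_cap_cycles(self):
        # floor(2 x 365.25 / 21) = 34 cycles within the 2-year rule
        assert atezolizumab_cap_cycles(RunConfig()) == 34
        assert atezolizumab_cap_cycles(RunConfig(atezolizumab_cap_years=None)) is None

    def test_pembrolizumab_cap_is_35_cycles(self):
        comp = next(c for c in regimen_components("PBC", RunConfig())
                    if c.drug == "pembrolizumab")
        assert comp.max_cycles == 35

    def test_unknown_rule_and_arm(self, patient):
        with pytest.raises(ValueError):
            RegimenComponent("x", "per_litre", 1.0, "p", 1.0, None).resolved_dose_mg(patient)
        with pytest.raises(ValueError):
            regimen_components("XYZ", RunConfig())

    def test_patient_validation(self):
        with pytest.raises(ValueError):
            Patient(weight_kg=-1)


class TestSAECosts:
    def test_bc_sum(self, values):
        # sum of incidence x unit cost over the five BC events
        expected = (0.09 * 9860.3 + 0.07 * 15960.2 + 0.25 * 11562.1
                    + 0.16 * 2814.5 + 0.06 * 14056.1)
        assert sae_cost("BC", values) == pytest.approx(expected)
        assert sae_cost("BC", values) == pytest.approx(6188.85, abs=0.01)

    def test_profiles_cover_arms(self, values):
        assert set(SAE_PROFILES) == {"BC", "ABC", "PBC"}
        assert len(SAE_PROFILES["ABC"]) == 7
        assert len(SAE_PROFILES["PBC"]) == 9
        for arm in SAE_PROFILES:
            assert sae_cost(arm, values) > 0


class TestCostComponents:
    def _components(self, arm, values, n=40, **occ_kw):
        cfg = RunConfig()
        occ = _flat_occupancy(n, **occ_kw)
        factors = np.ones(n)
        durations = np.full(n, cfg.cycle_length_years)
        return cost_components(arm, occ, values, cfg, factors, durations), occ, cfg

    def test_chemo_stops_after_six_cycles(self, values, patient):
        comps, occ, cfg = self._components("BC", values)
        acq = comps["acquisition"]
        parts = {c.drug: drug_cost_per_cycle(c, patient, values)
                 for c in regimen_components("BC", cfg)}
        full = sum(parts.values())
        assert acq[0] == pytest.approx(full)
        assert acq[5] == pytest.approx(full)
        assert acq[6] == pytest.approx(parts["bevacizumab"])

    def test_atezolizumab_stops_at_cap(self, values, patient):
        comps, occ, cfg = self._components("ABC", values)
        acq = comps["acquisition"]
        atez = next(c for c in regimen_components("ABC", cfg)
                    if c.drug == "atezolizumab")
        price = drug_cost_per_cycle(atez, patient, values)
        assert acq[33] - acq[34] == pytest.approx(price)

    def test_uncapped_atezolizumab_never_stops(self, values):
        cfg = RunConfig(atezolizumab_cap_years=None)
        n = 60
        occ = _flat_occupancy(n)
        comps = cost_components("ABC", occ, values, cfg, np.ones(n),
                                np.full(n, cfg.cycle_length_years))
        acq = comps["acquisition"]
        assert acq[34] == pytest.approx(acq[59])

    def test_no_acquisition_when_no_one_progression_free(self, values):
        comps, occ, _ = self._components("BC", values, pfs=0.0, pd=0.5)
        assert np.all(comps["acquisition"][1:] == 0)
        assert np.all(comps["administration"][1:] == 0)
        assert np.all(comps["post_progression"][1:] > 0)

    def test_sae_cost_only_at_cycle_zero(self, values):
        comps, _, _ = self._components("PBC", values)
        assert comps["sae"][0] == pytest.approx(sae_cost("PBC", values))
        assert np.all(comps["sae"][1:] == 0)

    def test_end_of_life_conservation(self, values):
        # everyone eventually dies -> total EoL cost = unit cost
        n = 40
        os_v = np.linspace(1.0, 0.0, n)
        occ = compute_occupancy(os_v, os_v)
        cfg = RunConfig()
        comps = cost_components("BC", occ, values, cfg, np.ones(n),
                                np.full(n, cfg.cycle_length_years))
        assert comps["end_of_life"].sum() == pytest.approx(
            values["Cost_end-of-life care"])

    def test_post_progression_mix(self, values):
        comps, occ, cfg = self._components("BC", values, pfs=0.4, pd=0.5)
        p = values["Subsequent active treatment_BC"]
        per_pd = (p * values["Subsequent active treatment cost"]
                  + (1 - p) * values["Cost_best supportive care"])
        assert comps["post_progression"][3] == pytest.approx(0.5 * per_pd)

    def test_follow_up_tracks_all_alive(self, values):
        comps, occ, _ = self._components("BC", values, pfs=0.3, pd=0.4)
        assert comps["follow_up"][5] == pytest.approx(
            values["Follow-up cost"] * 0.7)


class TestQALYs:
    def test_cycle_arithmetic(self, values):
        cfg = RunConfig()
        n = 3
        occ = _flat_occupancy(n)
        q = qaly_trace("BC", occ, {**values, "SAE_BC": 0.0}, cfg,
                       np.ones(n), np.full(n, cfg.cycle_length_years))
        assert q[1] == pytest.approx(values["Utility_PFS"] * 21 / 365.25)

    def test_sae_disutility_first_cycle(self, values):
        cfg = RunConfig()
        n = 3
        occ = _flat_occupancy(n)
        dur = np.full(n, cfg.cycle_length_years)
        with_sae = qaly_trace("ABC", occ, values, cfg, np.ones(n), dur)
        without = qaly_trace("ABC", occ, {**values, "SAE_ABC": 0.0}, cfg,
                             np.ones(n), dur)
        loss = values["SAE_ABC"] * values["Disu_SAE"] * cfg.cycle_length_years
        assert without[0] - with_sae[0] == pytest.approx(loss)
        assert with_sae[1] == pytest.approx(without[1])

    def test_full_decrement_switch(self, values):
        cfg = RunConfig(sae_full_decrement=True)
        n = 3
        occ = _flat_occupancy(n)
        dur = np.full(n, cfg.cycle_length_years)
        q = qaly_trace("ABC", occ, values, cfg, np.ones(n), dur)
        base = qaly_trace("ABC", occ, {**values, "SAE_ABC": 0.0}, cfg,
                          np.ones(n), dur)
        assert base[0] - q[0] == pytest.approx(
            values["SAE_ABC"] * values["Disu_SAE"])

    def test_utility_above_one_rejected(self, values):
        cfg = RunConfig()
        occ = _flat_occupancy(3)
        with pytest.raises(ValueError, match="utilities"):
            qaly_trace("BC", occ, {**values, "Utility_PFS": 1.2}, cfg,
                       np.ones(3), np.full(3, cfg.cycle_length_years))


class TestIncrementalAnalysis:
    def test_simple_icer(self):
        table = icer_table({"A": (100.0, 1.0, 1.5), "B": (200.0, 2.0, 2.5)},
                           reference="A")
        row = table[table["arm"] == "B"].iloc[0]
        assert row["icer"] == pytest.approx(100.0)
        assert row["status"] == "icer"

    def test_dominance_statuses(self):
        table = icer_table(
            {"ref": (100.0, 1.0, 1.0),
             "dominant": (50.0, 2.0, 2.0),
             "dominated": (200.0, 0.5, 0.5),
             "equal": (150.0, 1.0, 1.0)},
            reference="ref",
        )
        status = dict(zip(table["arm"], table["status"]))
        assert status["dominant"] == "dominant"
        assert status["dominated"] == "dominated"
        assert "undefined" in status["equal"]

    def test_reference_validation(self):
        with pytest.raises(ValueError):
            icer_table({"A": (1.0, 1.0, 1.0)})
        with pytest.raises(ValueError):
            icer_table({"A": (1.0, 1.0, 1.0), "B": (2.0, 2.0, 2.0)},
                       reference="Z")

    def test_icer_monotone_in_drug_price(self, values, config):
        # doubling the pembrolizumab price must raise the PBC ICER
        from psmcea.psm import ModelRunner

        n = config.n_cycles
        bc = (np.linspace(1.0, 0.2, n), np.linspace(1.0, 0.1, n))
        abc = (np.linspace(1.0, 0.3, n), np.linspace(1.0, 0.15, n))
        runner = ModelRunner(bc, abc, config)

        def pbc_icer(price):
            totals = runner.run_totals({**values, "Cost_pembrolizumab_1 mg": price})
            t = icer_table(totals, reference="BC")
            return t[t["arm"] == "PBC"]["icer"].iloc[0]

        assert pbc_icer(2 * 56.7) > pbc_icer(56.7) > pbc_icer(0.5 * 56.7)

    def test_pairwise_covers_all_ordered_pairs(self):
        table = pairwise_icers({"A": (100.0, 1.0, 1.0), "B": (200.0, 2.0, 2.0),
                                "C": (300.0, 3.0, 3.0)})
        assert len(table) == 6
        ab = table[(table["arm"] == "B") & (table["vs"] == "A")].iloc[0]
        assert ab["icer"] == pytest.approx(100.0)

    def test_frontier_extended_dominance(self):
        # B's incremental ratio exceeds the next step's: extendedly dominated
        table = efficiency_frontier(
            {"A": (0.0, 0.0, 0.0), "B": (150.0, 1.0, 1.0), "C": (200.0, 2.0, 2.0)}
        )
        status = dict(zip(table["arm"], table["status"]))
        assert status["A"] == "on frontier"
        assert status["B"] == "extendedly dominated"
        assert status["C"] == "on frontier"

    def test_frontier_simple_dominance(self):
        table = efficiency_frontier(
            {"A": (0.0, 1.0, 1.0), "B": (100.0, 0.5, 0.5)}
        )
        status = dict(zip(table["arm"], table["status"]))
        assert status["B"] == "dominated"
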