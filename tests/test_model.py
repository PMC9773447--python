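import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from dsbfold.disulfides import Category
from dsbfold.model import (
    CATS,
    DsbFoldingModel,
    ModelParameters,
    ModelState,
    SubstrateClass,
    accumulation_fraction,
    association_rate_to_cell_units,
    association_rate_to_molar_units,
    build_model,
    proteome_doubling_time,
    simulate,
    substrate_influx_rates,
)
from dsbfold.sbml import to_reaction_text, to_sbml


def make_params(v=(10.0, 5.0, 2.0), k45=0.01, k678=0.01, k2=50.0, k3=0.005,
                k9=0.005, k10=50.0):
    return ModelParameters(
        k2=k2, k3=k3,
        k45={c: k45 for c in CATS},
        k678={Category.CAT2: k678, Category.CAT3: k678},
        k9=k9, k10=k10,
        v_syn=dict(zip(CATS, v)),
    )


def make_model(params=None, pools=(2000.0, 500.0, 600.0, 100.0)):
    params = params or make_params()
    return build_model(params, ModelState.fresh(*pools))


class TestConstruction:
    def test_fraction_sum_must_be_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ModelParameters(
                k2=1, k3=1, k45={c: 1 for c in CATS},
                k678={Category.CAT2: 1, Category.CAT3: 1}, k9=1, k10=1,
                v_syn={c: 0 for c in CATS},
                f_futile=0.5, f_success=0.5, f_reduce=0.5,
            )

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            make_params(k2=-1.0)

    def test_rate_vector_round_trip(self):
        params = make_params()
        rates = params.rate_vector()
        assert np.allclose(params.with_rate_vector(rates).rate_vector(), rates)


class TestDynamics:
    def test_null_dynamics_stays_constant(self):
        params = make_params(v=(0.0, 0.0, 0.0))
        traj = simulate(make_model(params), 50.0, n_points=20)
        first, last = traj.states.iloc[0], traj.states.iloc[-1]
        assert np.allclose(first.to_numpy(), last.to_numpy(), atol=1e-9)

    def test_cat1_only_influx_never_uses_isomerase(self):
        params = make_params(v=(10.0, 0.0, 0.0))
        traj = simulate(make_model(params), 100.0)
        assert traj.states[["MFP_cat1", "MFP_cat2", "MFP_cat3"]].to_numpy().max() < 1e-9
        iso_cols = ["R6_cat2", "R6_cat3", "R7_cat2", "R7_cat3", "R8_cat2", "R8_cat3", "R9", "R10"]
        assert traj.fluxes[iso_cols].to_numpy().max() < 1e-9

    def test_explicit_euler_oracle(self):
        """Independent Euler integration of the written-out rate equations."""
        params = make_params()
        pools = (2000.0, 500.0, 600.0, 100.0)
        model = make_model(params, pools)
        horizon, dt = 5.0, 5e-5
        a_tot, b_tot, cg_tot, d_tot = pools
        uf = np.zeros(3); mfp = np.zeros(3); fp = np.zeros(3)
        ao, bo, cgr, dr = a_tot, b_tot, cg_tot, d_tot
        v = np.array([10.0, 5.0, 2.0])
        p = np.array([1.0, 0.5, 0.0])
        k45 = np.full(3, 0.01); k678 = np.array([0.0, 0.01, 0.01])
        fs = fr = 1.0 / 3.0
        for _ in range(int(horizon / dt)):
            r45 = k45 * uf * ao
            r678 = k678 * mfp * cgr
            r3 = 0.005 * (a_tot - ao) * bo
            r2 = 50.0 * (b_tot - bo)
            r9 = 0.005 * (cg_tot - cgr) * dr
            r10 = 50.0 * (d_tot - dr)
            uf = uf + dt * (v - r45 + fr * r678)
            mfp = mfp + dt * ((1 - p) * r45 - (fs + fr) * r678)
            fp = fp + dt * (p * r45 + fs * r678)
            ao += dt * (r3 - r45.sum())
            bo += dt * (r2 - r3)
            cgr += dt * (r9 - fr * r678.sum())
            dr += dt * (r10 - r9)
        traj = simulate(model, horizon, n_points=2, rtol=1e-10)
        end = traj.states.iloc[-1]
        for i, cat in enumerate(CATS):
            assert end[f"UF_{cat.value}"] == pytest.approx(uf[i], rel=1e-3, abs=1e-6)
            assert end[f"MFP_{cat.value}"] == pytest.approx(mfp[i], rel=1e-3, abs=1e-6)
            assert end[f"FP_{cat.value}"] == pytest.approx(fp[i], rel=1e-3, abs=1e-6)
        assert end["DsbAo"] == pytest.approx(ao, rel=1e-3)
        assert end["DsbCGr"] == pytest.approx(cgr, rel=1e-3)

    def test_moiety_conservation_exact(self):
        traj = simulate(make_model(), 200.0)
        for name, drift in traj.conservation_drift().items():
            assert drift <= 1e-12, name

    def test_steady_state_flux_balance(self):
        model = make_model()
        ss = model.find_steady_state(warmup=2000.0)
        fluxes = model.fluxes(ss)
        r45 = fluxes[[f"R4_{c.value}" for c in CATS]].sum() + fluxes[
            [f"R5_{c.value}" for c in CATS]
        ].sum()
        r8 = fluxes[["R8_cat2", "R8_cat3"]].sum()
        assert fluxes["R2"] == pytest.approx(fluxes["R3"], rel=1e-6)
        assert fluxes["R3"] == pytest.approx(r45, rel=1e-6)
        assert fluxes["R9"] == pytest.approx(r8, rel=1e-6)
        assert fluxes["R10"] == pytest.approx(r8, rel=1e-6)

    def test_category_relabel_symmetry(self):
        """Identical parameters in two categories give identical trajectories."""
        params = ModelParameters(
            k2=50.0, k3=0.005,
            k45={Category.CAT1: 0.01, Category.CAT2: 0.02, Category.CAT3: 0.02},
            k678={Category.CAT2: 0.01, Category.CAT3: 0.01},
            k9=0.005, k10=50.0,
            v_syn={Category.CAT1: 0.0, Category.CAT2: 5.0, Category.CAT3: 5.0},
            p_correct={Category.CAT1: 1.0, Category.CAT2: 0.3, Category.CAT3: 0.3},
        )
        traj = simulate(make_model(params), 100.0)
        for prefix in ("UF", "MFP", "FP"):
            np.testing.assert_allclose(
                traj.states[f"{prefix}_cat2"], traj.states[f"{prefix}_cat3"],
                rtol=1e-9, atol=1e-9,
            )


class TestInflux:
    def test_dilution_balance(self):
        v = substrate_influx_rates({Category.CAT1: 1000.0, Category.CAT2: 0.0,
                                    Category.CAT3: 0.0}, mu=0.6931)
        assert v[Category.CAT1] * 60 == pytest.approx(693.1)  # bonds/cell/h

    def test_linearity_in_growth_rate(self):
        demand = {Category.CAT1: 500.0, Category.CAT2: 300.0, Category.CAT3: 100.0}
        v1 = substrate_influx_rates(demand, 0.4)
        v2 = substrate_influx_rates(demand, 0.8)
        for cat in CATS:
            assert v2[cat] == pytest.approx(2 * v1[cat])

    def test_per_category_product_oracle(self):
        demand = {Category.CAT1: 123.0, Category.CAT2: 456.0, Category.CAT3: 789.0}
        v = substrate_influx_rates(demand, 0.9)
        for cat, bonds in demand.items():
            assert v[cat] == pytest.approx(0.9 / 60 * bonds)

    def test_zero_growth_rejected(self):
        with pytest.raises(ValueError):
            substrate_influx_rates({c: 1.0 for c in CATS}, 0.0)


class TestAccumulationAndDoubling:
    def test_fast_enzymes_accumulate_nothing(self):
        traj = simulate(make_model(make_params(k45=10.0)), 100.0)
        assert accumulation_fraction(traj, Category.CAT1) < 1e-3

    def test_absent_enzymes_accumulate_everything(self):
        traj = simulate(make_model(make_params(), pools=(0.0, 0.0, 0.0, 0.0)), 500.0)
        assert accumulation_fraction(traj, 1) == pytest.approx(1.0)
        assert accumulation_fraction(traj, 3) == pytest.approx(1.0)

    def test_integral_oracle(self):
        traj = simulate(make_model(), 60.0, n_points=500)
        cat = Category.CAT3
        backlog = (
            traj.states["UF_cat3"].iloc[-1] + traj.states["MFP_cat3"].iloc[-1]
        )
        synthesised = 2.0 * 60.0  # v_syn_cat3 * horizon
        assert accumulation_fraction(traj, cat) == pytest.approx(
            backlog / synthesised, rel=1e-6
        )

    def test_zero_synthesis_defined_as_zero(self):
        traj = simulate(make_model(make_params(v=(0.0, 0.0, 0.0))), 10.0)
        assert accumulation_fraction(traj, 1) == 0.0

    def test_unconstrained_doubling_time_is_ln2_over_mu(self):
        mu = 0.7
        demand = {Category.CAT1: 5000.0, Category.CAT2: 0.0, Category.CAT3: 0.0}
        v = substrate_influx_rates(demand, mu)
        params = make_params(v=tuple(v.values()), k45=1.0)
        traj = simulate(make_model(params), 120.0, n_points=1000)
        td = proteome_doubling_time(traj, demand)
        assert td == pytest.approx(60 * math.log(2) / mu, rel=2e-2)

    def test_slower_oxidase_lengthens_doubling(self):
        mu = 0.7
        demand = {Category.CAT1: 5000.0, Category.CAT2: 0.0, Category.CAT3: 0.0}
        v = substrate_influx_rates(demand, mu)
        times = []
        for k45 in (2e-3, 1e-3):
            params = make_params(v=tuple(v.values()), k45=k45)
            traj = simulate(make_model(params), 400.0, n_points=2000)
            times.append(proteome_doubling_time(traj, demand))
        assert times[1] > times[0]

    def test_zero_influx_sentinel(self):
        traj = simulate(make_model(make_params(v=(0.0, 0.0, 0.0))), 10.0)
        assert proteome_doubling_time(traj, {Category.CAT1: 100.0,
                                             Category.CAT2: 0.0,
                                             Category.CAT3: 0.0}) == math.inf


class TestExtraSubstrates:
    def test_extra_class_consumes_shared_enzymes(self):
        params = make_params()
        extra = SubstrateClass(v_syn=20.0, k45=0.01, k678=0.01, p_correct=0.0)
        base = make_model(params)
        loaded = DsbFoldingModel(params, base.initial, extra_classes=[extra])
        sol_base = base.simulate(50.0, n_points=2)
        sol_loaded = loaded.simulate(50.0, n_points=2)
        # native cat3 backlog grows when a recombinant competitor is added
        backlog_base = sol_base.y[2, -1] + sol_base.y[5, -1]
        backlog_loaded = sol_loaded.y[2, -1] + sol_loaded.y[6, -1]
        assert backlog_loaded > backlog_base


class TestUnitsAndExport:
    def test_association_rate_round_trip(self):
        volume = 2.62e-15 * 0.2
        k_cell = association_rate_to_cell_units(1e6, volume)
        assert association_rate_to_molar_units(k_cell, volume) == pytest.approx(1e6)

    def test_sbml_is_well_formed_and_complete(self):
        model = make_model()
        doc = ET.fromstring(to_sbml(model))
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        species = doc.findall(".//s:species", ns)
        reactions = doc.findall(".//s:reaction", ns)
        assert len(species) == 17  # 9 substrate pools + 8 enzyme forms
        ids = {r.get("id") for r in reactions}
        assert {"R2", "R3", "R9", "R10", "R4_cat1", "R5_cat3", "R8_cat2"} <= ids

    def test_reaction_text_lists_all_reactions(self):
        text = to_reaction_text(make_model())
        for token in ("R1_cat1", "R2:", "R3:", "R6/7/8_cat3", "R10:"):
            assert token in text
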