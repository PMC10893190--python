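"""ODE engine checks against closed-form pharmacokinetic oracles.

The independent oracles are analytic: for a linear drug the systemic AUC0–∞
after an i.v. dose equals dose divided by the sum of the well-stirred
hepatic and flow-limited renal (and biliary) blood clearances, and at
steady state under constant infusion the organ clearances equal those
closed forms exactly.
"""

import numpy as np
import pytest

from ces1pbpk import (DoseRegimen, SimOptions, ValidationError, build_system,
                      flow_limited_cl, load_drug, mass_balance, mm_to_clint,
                      simulate, well_stirred_cl)


def closed_form_cl_blood(rec, phys):
    """Total blood clearance of a linear(ized) record: well-stirred hepatic
    (all pathways + biliary) plus flow-limited renal."""
    clint = 0.0
    for pw in rec.pathways:
        if pw.is_saturable:
            clint += mm_to_clint(pw.vmax, pw.km, SimOptions().mppgl, phys.v_liver)
        else:
            clint += pw.clint
    clint += rec.cl_bile or 0.0
    cl = well_stirred_cl(clint, rec.fu_b, phys.q_l) if clint else 0.0
    if rec.clint_k:
        cl += flow_limited_cl(rec.clint_k, rec.fu_b, phys.q_k)
    return cl


def blood_auc_inf(res, name, rb):
    """AUC0–∞ of the blood curve (mg·min/mL): trapezoid plus a log-linear
    tail fitted where the curve is still well above the solver noise floor."""
    c = res.conc[name] * rb / 1e6  # mg/mL blood
    resolved = np.flatnonzero(c >= c.max() * 1e-7)
    i = resolved[-1]
    lz = -np.polyfit(res.t[i - 3:i + 1], np.log(c[i - 3:i + 1]), 1)[0]
    return np.trapezoid(c[:i + 1], res.t[:i + 1]) + c[i] / lz


class TestClosedFormAUC:
    @pytest.mark.parametrize("name,t_end", [
        ("remimazolam", 30_000), ("flumazenil", 6_000),
        ("enalapril", 4_000), ("oseltamivir", 20_000),
    ])
    def test_iv_auc_equals_dose_over_clearance(self, drugs, healthy, name, t_end):
        rec = drugs[name]
        # default output grid: 0.1-min refinement over the dosing phase, so
        # the trapezoid resolves fast distribution phases
        res = simulate(build_system(rec, healthy, DoseRegimen(route="iv_bolus", amount=5.0)),
                       t_end)
        auc_b = blood_auc_inf(res, name, rec.rb)
        assert 5.0 / auc_b == pytest.approx(closed_form_cl_blood(rec, healthy), rel=5e-3)

    def test_pethidine_linear_limit(self, drugs, healthy):
        # a microdose keeps both saturable pathways far below Km
        rec = drugs["pethidine"]
        res = simulate(build_system(rec, healthy, DoseRegimen(route="iv_bolus", amount=0.1)),
                       60_000, grid=15.0)
        auc_b = blood_auc_inf(res, "pethidine", rec.rb)
        assert 0.1 / auc_b == pytest.approx(closed_form_cl_blood(rec, healthy), rel=5e-3)


class TestSteadyState:
    def test_hepatic_and_renal_clearances_match_closed_forms(self, drugs, healthy):
        rec = drugs["enalapril"]
        t_end = 20_000.0
        reg = DoseRegimen(route="iv_infusion", amount=100.0, infusion_duration=t_end)
        sys_ = build_system(rec, healthy, reg)
        res = simulate(sys_, t_end, grid=20.0)
        # steady state: derivative-free amounts over the last stretch
        c_sys = res.conc["enalapril"][-1] * rec.rb / 1e6  # mg/mL blood
        s = sys_.species[0]
        c_liv_out = (res.amounts["enalapril:liver"][-1] / healthy.v_liver) * rec.rb / rec.k_lp
        c_k_out = (res.amounts["enalapril:kidney"][-1] / healthy.v_k) * rec.rb / rec.k_kp
        extraction = rec.fu_b * 784 * c_liv_out / (healthy.q_l * c_sys)
        expected_e = rec.fu_b * 784 / (healthy.q_l + rec.fu_b * 784)
        assert extraction == pytest.approx(expected_e, rel=1e-2)
        renal_cl = rec.clint_k * rec.fu_b * c_k_out / c_sys
        assert renal_cl == pytest.approx(
            flow_limited_cl(rec.clint_k, rec.fu_b, healthy.q_k), rel=1e-2)


class TestMassBalance:
    @pytest.mark.parametrize("name", ["enalapril", "benazepril", "cilazapril",
                                      "perindopril", "temocapril", "oseltamivir",
                                      "flumazenil", "pethidine", "remimazolam"])
    def test_closure_for_every_fixture_drug(self, drugs, healthy, name):
        rec = drugs[name]
        route = "oral" if rec.has_absorption else "iv_bolus"
        res = simulate(build_system(rec, healthy, DoseRegimen(route=route, amount=10.0)),
                       2880, grid=5.0)
        assert mass_balance(res) < 1e-3

    def test_closure_mid_infusion(self, drugs, healthy):
        reg = DoseRegimen(route="iv_infusion", amount=10.0, infusion_duration=600.0)
        res = simulate(build_system(drugs["flumazenil"], healthy, reg), 300.0, grid=1.0)
        assert mass_balance(res) < 1e-3

    def test_unaccounted_loss_is_caught(self, drugs, healthy):
        # negative control: an uncounted first-order leak from the systemic
        # pool must show up as a mass-balance violation
        sys_ = build_system(drugs["remimazolam"], healthy,
                            DoseRegimen(route="iv_bolus", amount=10.0))
        i_sys = sys_.species[0].idx["sys"]
        orig_rhs = sys_.rhs

        def leaky(t, y):
            dy = orig_rhs(t, y)
            dy[i_sys] -= 0.01 * y[i_sys]
            return dy

        sys_.rhs = leaky
        res = simulate(sys_, 1440, grid=5.0)
        assert mass_balance(res) > 1e-3


class TestLinearityAndStructure:
    def test_dose_linearity_for_linear_drugs(self, drugs, healthy):
        for name in ("enalapril", "oseltamivir"):
            aucs = []
            for dose in (1.0, 20.0):
                res = simulate(build_system(drugs[name], healthy,
                                            DoseRegimen(route="oral", amount=dose)),
                               1440, grid=2.0)
                aucs.append(np.trapezoid(res.conc[name], res.t) / dose)
            assert aucs[0] == pytest.approx(aucs[1], rel=1e-3)

    def test_pethidine_clearance_decreases_with_dose(self, drugs, healthy):
        cls = []
        for dose in (25.0, 50.0, 100.0):
            res = simulate(build_system(drugs["pethidine"], healthy,
                                        DoseRegimen(route="iv_bolus", amount=dose)),
                           10_000, grid=10.0)
            cls.append(dose / blood_auc_inf(res, "pethidine", drugs["pethidine"].rb))
        assert cls[0] > cls[1] > cls[2]

    def test_metabolite_mass_conservation(self, drugs, healthy):
        res = simulate(build_system(drugs["enalapril"], healthy,
                                    DoseRegimen(route="oral", amount=10.0)),
                       20_000, grid=20.0)
        formed = res.eliminated["enalapril:elim_CES1"][-1]
        met_total = (res.amounts["enalaprilat:sys"][-1]
                     + res.amounts["enalaprilat:per1"][-1]
                     + res.amounts["enalaprilat:liver"][-1]
                     + res.amounts["enalaprilat:kidney"][-1]
                     + res.amounts["enalaprilat:pv"][-1]
                     + sum(res.amounts[f"enalaprilat:gw_{s}"][-1]
                           for s in ("duodenum", "jejunum", "ileum"))
                     + res.eliminated["enalaprilat:renal"][-1]
                     + res.eliminated["enalaprilat:bile"][-1])
        assert met_total == pytest.approx(formed, rel=1e-3)

    def test_oral_exposure_never_exceeds_iv(self, drugs, healthy):
        for name in ("enalapril", "flumazenil", "temocapril"):
            rec = drugs[name]
            auc = {}
            for route in ("oral", "iv_bolus"):
                res = simulate(build_system(rec, healthy,
                                            DoseRegimen(route=route, amount=10.0)),
                               2880, grid=5.0)
                auc[route] = np.trapezoid(res.conc[name], res.t)
            assert auc["oral"] <= auc["iv_bolus"]

    def test_no_dose_means_no_drug(self, drugs, healthy):
        sys_ = build_system(drugs["enalapril"], healthy,
                            DoseRegimen(route="oral", amount=10.0))
        sys_.y0[:] = 0.0
        res = simulate(sys_, 720, grid=5.0)
        assert np.all(res.conc["enalapril"] == 0)
        assert np.all(res.conc["enalaprilat"] == 0)

    def test_state_layout(self, drugs, healthy):
        # i.v.-only drug: no lumen chain, two peripheral compartments
        sys_iv = build_system(drugs["remimazolam"], healthy,
                              DoseRegimen(route="iv_bolus", amount=7.0))
        assert not any("lumen" in lab or "stomach" in lab for lab in sys_iv.labels)
        assert "remimazolam:per1" in sys_iv.labels and "remimazolam:per2" in sys_iv.labels
        # oral parent + metabolite: 11 parent and 8 metabolite dynamic states
        sys_oral = build_system(drugs["enalapril"], healthy,
                                DoseRegimen(route="oral", amount=10.0))
        dynamic = [lab for lab in sys_oral.labels
                   if "elim" not in lab and "fecal" not in lab and "formed" not in lab]
        assert len([x for x in dynamic if x.startswith("enalapril:")]) == 11
        assert len([x for x in dynamic if x.startswith("enalaprilat:")]) == 8

    def test_oral_route_requires_absorption_parameter(self, drugs, healthy):
        with pytest.raises(ValidationError, match="Peff"):
            build_system(drugs["remimazolam"], healthy,
                         DoseRegimen(route="oral", amount=10.0))

    def test_missing_metabolite_record_rejected(self, drugs, healthy):
        rec = drugs["enalapril"].copy()
        rec.metabolite = None
        with pytest.raises(ValidationError, match="metabolite"):
            build_system(rec, healthy, DoseRegimen(route="oral", amount=10.0))
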