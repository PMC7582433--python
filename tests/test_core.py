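"""Structural properties of the PBPK right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pbpkddi.core import (IDX, N_STATE, DrugModel, InhibitorExposure,
                          JointModel, inhibition_factor)
from pbpkddi.params import DrugParams


# ---------------------------------------------------------------------------
# Inhibition factor

def test_inhibition_factor_values():
    assert inhibition_factor(0.0, 10.0) == 1.0
    assert inhibition_factor(10.0, 10.0) == 2.0
    # unbound CsA at exactly Ki,OATP (0.014 uM x 1202.61 g/mol = 16.84 ng/mL)
    ki_oatp = 0.014 * 1202.61
    assert inhibition_factor(ki_oatp, ki_oatp) == pytest.approx(2.0)


def test_inhibition_factor_contract():
    with pytest.raises(ValueError):
        inhibition_factor(1.0, 0.0)
    with pytest.raises(ValueError):
        inhibition_factor(-1.0, 1.0)


@settings(max_examples=100, deadline=None)
@given(c=st.floats(0, 1e9), ki=st.floats(1e-6, 1e9))
def test_inhibition_factor_at_least_one(c, ki):
    assert inhibition_factor(c, ki) >= 1.0


# ---------------------------------------------------------------------------
# Right-hand side

@pytest.fixture(scope="module")
def models(drugs, physio):
    return {n: DrugModel(d, physio) for n, d in drugs.items()}


def test_zero_state_zero_derivative(models):
    y = np.zeros(N_STATE)
    for m in models.values():
        assert np.all(m.rhs(y) == 0.0)


def test_stomach_bolus_empties_into_duodenum(models):
    y = np.zeros(N_STATE)
    y[IDX["stomach"]] = 1e6
    dy = models["cyclosporine"].rhs(y)
    assert dy[IDX["stomach"]] == pytest.approx(-0.0462 * 1e6)
    assert dy[IDX["lumen_duodenum"]] == pytest.approx(0.0462 * 1e6)


@pytest.mark.parametrize("name", ["cyclosporine", "atorvastatin", "pravastatin",
                                  "rosuvastatin", "bosentan"])
def test_rhs_conserves_mass(name, models):
    rng = np.random.default_rng(42)
    m = models[name]
    for _ in range(5):
        y = rng.uniform(0.0, 1e7, N_STATE)
        dy = m.rhs(y)
        assert abs(dy.sum()) <= 1e-8 * np.abs(dy).max()


@settings(max_examples=50, deadline=None)
@given(y=arrays(np.float64, N_STATE, elements=st.floats(0, 1e8)))
def test_rhs_mass_balance_property(y, drugs, physio):
    m = DrugModel(drugs["atorvastatin"], physio)
    dy = m.rhs(y)
    scale = max(np.abs(dy).max(), 1.0)
    assert abs(dy.sum()) <= 1e-8 * scale


def test_rhs_conserves_mass_under_inhibition(models, inhibition, drugs, physio):
    m = DrugModel(drugs["atorvastatin"], physio, inhibition=inhibition)
    exp = InhibitorExposure(gut_wall=np.array([50.0, 100.0, 75.0]),
                           liver_blood_u=30.0, hepatocyte_u=80.0, kidney_u=10.0)
    rng = np.random.default_rng(3)
    y = rng.uniform(0.0, 1e7, N_STATE)
    dy = m.rhs(y, exp)
    assert abs(dy.sum()) <= 1e-8 * np.abs(dy).max()


def test_active_uptake_is_linear_in_sf(drugs, physio):
    """Doubling SF_act adds exactly SF*CLint,up,OATP of flux per unit unbound
    hepatic-blood concentration."""
    ato = drugs["atorvastatin"]
    m1 = DrugModel(ato, physio)
    m2 = DrugModel(ato.copy(sf_act=2 * ato.sf_act), physio)
    y = np.zeros(N_STATE)
    y[IDX["liver_blood"]] = physio.v_liver_blood / ato.fub  # unbound conc 1 ng/mL
    extra = m2.rhs(y)[IDX["hepatocytes"]] - m1.rhs(y)[IDX["hepatocytes"]]
    assert extra == pytest.approx(32.6 * 6374.7, rel=1e-9)


def test_enterocyte_inhibitor_reduces_apical_efflux(drugs, physio, inhibition):
    m = DrugModel(drugs["atorvastatin"], physio, inhibition=inhibition)
    y = np.zeros(N_STATE)
    y[IDX["gw_jejunum"]] = 1e6
    lum = IDX["lumen_jejunum"]
    no_inh = m.rhs(y)[lum]
    with_inh = m.rhs(y, InhibitorExposure(gut_wall=np.array([0, 1e4, 0.0])))[lum]
    assert 0 < with_inh < no_inh


def test_renal_secretion_inhibited_via_secretory_transporter_only(
        drugs, physio, inhibition):
    """Rosuvastatin renal secretion responds to kidney exposure through
    Ki,BCRP; disabling the BCRP flag removes the effect."""
    ros = drugs["rosuvastatin"]
    y = np.zeros(N_STATE)
    y[IDX["kidney"]] = 1e6
    base = DrugModel(ros, physio, inhibition=inhibition)
    exp = InhibitorExposure(kidney_u=1e4)
    assert base.rhs(y, exp)[IDX["urine"]] < base.rhs(y)[IDX["urine"]]
    off = DrugModel(ros, physio,
                    inhibition=inhibition.copy(enabled={"bcrp": False}))
    assert off.rhs(y, exp)[IDX["urine"]] == pytest.approx(base.rhs(y)[IDX["urine"]])


def test_huge_ki_recovers_uninhibited_kidney(drugs, physio, inhibition):
    ros = drugs["rosuvastatin"]
    loose = inhibition.copy(ki_um={k: 1e12 for k in inhibition.ki_um})
    m = DrugModel(ros, physio, inhibition=loose)
    y = np.zeros(N_STATE)
    y[IDX["kidney"]] = 1e6
    exp = InhibitorExposure(kidney_u=1e4)
    assert m.rhs(y, exp)[IDX["urine"]] == pytest.approx(
        DrugModel(ros, physio).rhs(y)[IDX["urine"]], rel=1e-9)


def test_distribution_equilibrium_is_fixed_point(physio):
    """With no elimination and tissue amounts at K_tissue:b times the blood
    concentration, every derivative vanishes."""
    drug = DrugParams(
        name="tracer", fub=0.5, rb=0.8,
        kp={t: k for t, k in zip(
            ("adipose", "liver", "muscle", "lung", "kidney", "brain", "heart",
             "intestine", "skin", "spleen", "stomach", "rest"),
            (2.0, 3.0, 1.5, 0.9, 1.2, 0.7, 1.1, 2.5, 1.3, 0.6, 1.0, 1.0))},
        ka_direct=0.0, clint_pd=500.0,  # passive liver exchange, no clearance
        clint_gfr=0.0,
    )
    m = DrugModel(drug, physio)
    c = 10.0  # blood concentration ng/mL
    y = np.zeros(N_STATE)
    v = physio.tissue_volumes
    y[IDX["artery"]] = c * v["artery"]
    y[IDX["venous"]] = c * v["venous"]
    for tis in ("lung", "heart", "brain", "muscle", "skin", "adipose", "spleen",
                "kidney"):
        y[IDX[tis]] = c * v[tis] * drug.k_tissue_blood(tis)
    y[IDX["rob"]] = c * v["rob"] * drug.k_tissue_blood("rest")
    for seg in ("duodenum", "jejunum", "ileum"):
        y[IDX[f"gw_{seg}"]] = c * v[seg] * drug.k_tissue_blood("intestine")
    y[IDX["liver_blood"]] = c * physio.v_liver_blood
    y[IDX["hepatocytes"]] = c * physio.v_hepatocytes * drug.k_tissue_blood("liver")
    dy = m.rhs(y)
    assert np.abs(dy).max() <= 1e-9 * c * physio.cardiac_output


def test_system_matrix_columns_conserve_mass(drugs, physio):
    m = DrugModel(drugs["cyclosporine"], physio).system_matrix()
    assert np.abs(m.sum(axis=0)).max() <= 1e-10 * np.abs(m).max()


def test_joint_rhs_rejects_bad_length(drugs, physio, inhibition):
    victim = DrugModel(drugs["atorvastatin"], physio, inhibition=inhibition)
    joint = JointModel(victim, DrugModel(drugs["cyclosporine"], physio))
    with pytest.raises(ValueError):
        joint.rhs(np.zeros(N_STATE))


def test_joint_mass_balance_per_drug(drugs, physio, inhibition):
    victim = DrugModel(drugs["atorvastatin"], physio, inhibition=inhibition)
    joint = JointModel(victim, DrugModel(drugs["cyclosporine"], physio))
    rng = np.random.default_rng(11)
    y = rng.uniform(0.0, 1e7, 2 * N_STATE)
    dy = joint.rhs(y)
    assert abs(dy[:N_STATE].sum()) <= 1e-8 * np.abs(dy).max()
    assert abs(dy[N_STATE:].sum()) <= 1e-8 * np.abs(dy).max()
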