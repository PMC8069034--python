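import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from il13pkpd.model_core import (
    A_CX,
    A_CXP,
    C_IL13,
    DoseEvent,
    StructuralParams,
    baseline_il13,
    detected_il13,
    dissociation_constant,
    pd_response_basis,
    pk_concentration,
    rhs,
    simulate_subject,
)

TINY = 1e-15


def _params(**kw):
    base = dict(ka=0.156, cl_f=0.441, v2_f=2.83, v3_f=8.03, q_f=0.825,
                kin=0.0173, kout=180.0, kon=138.24, koff=0.69, vcx_f=13.6,
                fr=0.0429)
    base.update(kw)
    return StructuralParams(**base)


class TestDerivedQuantities:
    def test_kd_matches_biacore_affinity(self, ref_params):
        # Koff/Kon = 0.69/138.24 nM ~ 5 pM
        assert dissociation_constant(ref_params) == pytest.approx(
            0.004991, rel=1e-3)

    @pytest.mark.parametrize("kon, koff, kd", [(2.0, 1.0, 0.5), (1.0, 0.0, 0.0)])
    def test_kd_arithmetic(self, kon, koff, kd):
        assert dissociation_constant(_params(kon=kon, koff=koff)) == kd

    def test_baseline_reference_value(self, ref_params):
        # Kin/Kout = 0.0173/180 nM = 0.0961 pM
        assert baseline_il13(ref_params) == pytest.approx(9.611e-5, rel=1e-3)

    @pytest.mark.parametrize("kin, kout, b", [(0.0, 5.0, 0.0), (3.0, 3.0, 1.0)])
    def test_baseline_arithmetic(self, kin, kout, b):
        assert baseline_il13(_params(kin=kin, kout=kout)) == b

    def test_detected_limits(self):
        assert detected_il13(2.0, 5.0, 0.0) == 2.0
        assert detected_il13(2.0, 5.0, 1.0) == 7.0
        # mixed assay at the estimated fraction: ~4.9 pM for the QSS complex
        assert detected_il13(9.611e-5, 0.111, 0.0429) == pytest.approx(
            4.86e-3, rel=1e-2)

    def test_validation_rejects_bad_params(self):
        with pytest.raises(ValueError):
            _params(cl_f=-1.0)
        with pytest.raises(ValueError):
            _params(fr=1.5)
        with pytest.raises(ValueError):
            detected_il13(1.0, 1.0, -0.1)


class TestRHS:
    def test_zero_state_only_production(self, ref_params):
        d = rhs(0.0, np.zeros(6), ref_params)
        assert d[C_IL13] == pytest.approx(0.0173)
        d[C_IL13] = 0.0
        assert np.all(d == 0.0)

    @pytest.mark.parametrize("dissociation", [False, True])
    def test_baseline_is_steady_state(self, ref_params, dissociation):
        s = np.array([0, 0, 0, ref_params.baseline, 0, 0], dtype=float)
        d = rhs(0.0, s, ref_params, dissociation=dissociation)
        assert np.allclose(d, 0.0, atol=1e-15)

    def test_nonfinite_state_aborts(self, ref_params):
        with pytest.raises(FloatingPointError):
            rhs(0.0, np.array([np.nan, 0, 0, 0, 0, 0]), ref_params)


class TestSimulation:
    def test_no_dose_stays_flat_281_days(self, ref_params, grid_281):
        traj = simulate_subject(ref_params, [], grid_281)
        base = ref_params.baseline
        assert np.allclose(traj.free_il13, base, rtol=1e-7)
        assert np.allclose(traj.states[:, [0, 1, 2, 4, 5]], 0.0, atol=1e-10)
        assert np.allclose(traj.detected, base, rtol=1e-7)

    def test_quasi_steady_complex_under_sustained_drug(self, ref_params):
        # With drug clamped far above KD for the whole window the complex
        # settles at Kin*V2/CL = 0.0173*2.83/0.441 ~ 0.111 nM (~100 pM).
        grid = np.linspace(0, 281, 400)
        traj = simulate_subject(
            ref_params, [DoseEvent(0.0, 1e9)], grid)
        expected = ref_params.kin * ref_params.v2_f / ref_params.cl_f
        assert traj.complex_conc[-1] == pytest.approx(expected, rel=0.02)

    def test_pk_linearity_dose_proportional(self, ref_params, grid_281):
        t1 = simulate_subject(ref_params, [DoseEvent.from_mg(0.0, 105.0)],
                              grid_281)
        t2 = simulate_subject(ref_params, [DoseEvent.from_mg(0.0, 210.0)],
                              grid_281)
        mask = t1.drug_conc > 1e-12
        assert np.allclose(t2.drug_conc[mask] / t1.drug_conc[mask], 2.0,
                           rtol=1e-6)

    def test_analytic_pk_matches_ode(self, ref_params, grid_281):
        traj = simulate_subject(ref_params, [DoseEvent.from_mg(0.0, 105.0)],
                                grid_281)
        f = pk_concentration(grid_281, 700.0, ref_params.ka, ref_params.cl_f,
                             ref_params.v2_f, ref_params.v3_f, ref_params.q_f)
        assert np.allclose(traj.drug_conc, f, rtol=1e-6, atol=1e-10)

    def test_basis_matches_full_ode(self, ref_params):
        times = np.array([0, 1, 3, 8, 15, 29, 57, 113, 225, 281.0])
        traj = simulate_subject(ref_params, [DoseEvent(0.0, 700.0)], times,
                                rtol=1e-10, atol=1e-14)
        u, w = pd_response_basis(times, [(0.0, 700.0)], ref_params.ka,
                                 ref_params.cl_f, ref_params.v2_f,
                                 ref_params.v3_f, ref_params.q_f,
                                 ref_params.kout, ref_params.vcx_f,
                                 ref_params.kon)
        assert np.allclose(ref_params.kin * u, traj.free_il13, rtol=5e-4)
        assert np.allclose(ref_params.kin * w / ref_params.vcx_f,
                           traj.complex_conc, rtol=5e-4, atol=1e-12)

    def test_dose_after_start_leaves_predose_flat(self, ref_params):
        grid = np.linspace(0, 50, 200)
        traj = simulate_subject(ref_params, [DoseEvent(10.0, 700.0)], grid)
        pre = grid < 10
        assert np.allclose(traj.drug_conc[pre], 0.0, atol=1e-12)
        assert np.allclose(traj.free_il13[pre], ref_params.baseline, rtol=1e-7)
        assert traj.drug_conc[~pre].max() > 1.0

    def test_dose_outside_grid_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate_subject(ref_params, [DoseEvent(300.0, 1.0)],
                             np.linspace(0, 281, 10))

    def test_free_suppression_deep_while_drug_high(self, ref_params, grid_281):
        # the free-assay curve drops orders of magnitude below baseline
        traj = simulate_subject(ref_params, [DoseEvent.from_mg(0.0, 105.0)],
                                grid_281)
        assert traj.free_il13.min() < 0.05 * ref_params.baseline


class TestConservation:
    @pytest.mark.parametrize("dissociation", [False, True])
    def test_binding_subsystem_mass_balance(self, dissociation):
        # production, degradation and clearance switched (effectively) off;
        # a pre-loaded free IL13 bolus redistributes between free and bound
        # pools without mole loss.
        p = _params(cl_f=TINY, kin=0.0, kout=TINY, koff=0.69)
        y0 = np.array([0.0, 50.0 * p.v2_f, 0.0, 0.5, 0.2, 0.1])
        grid = np.linspace(0.0, 281.0, 300)
        traj = simulate_subject(p, [], grid, dissociation=dissociation,
                                initial_state=y0)
        total = (traj.states[:, C_IL13] * p.v2_f + traj.states[:, A_CX]
                 + traj.states[:, A_CXP])
        assert np.allclose(total, total[0], rtol=1e-6)

    def test_equilibrium_free_bound_ratio_is_kd_over_c(self):
        # reversible variant, constant drug, no elimination: the free/bound
        # concentration ratio converges to KD/C.
        conc = 2.0
        p = _params(ka=TINY, cl_f=TINY, q_f=TINY, kin=0.0, kout=TINY)
        y0 = np.array([0.0, conc * p.v2_f, 0.0, 1e-3, 0.0, 0.0])
        grid = np.linspace(0.0, 30.0, 100)
        traj = simulate_subject(p, [], grid, dissociation=True,
                                initial_state=y0)
        ratio = traj.free_il13[-1] / (traj.states[-1, A_CX] / p.v2_f)
        assert ratio == pytest.approx(p.kd / conc, rel=1e-4)


@settings(deadline=None, max_examples=30)
@given(fr_pair=st.tuples(st.floats(0, 1), st.floats(0, 1)))
def test_detected_monotone_in_fr(fr_pair):
    lo, hi = sorted(fr_pair)
    free = np.array([0.0, 1e-4, 0.01])
    cx = np.array([0.0, 0.05, 0.2])
    assert np.all(detected_il13(free, cx, lo) <= detected_il13(free, cx, hi))


def test_multi_dose_superposition(ref_params):
    # linear PK: two doses equal the sum of shifted single-dose profiles
    grid = np.linspace(0.0, 120.0, 400)
    two = simulate_subject(
        ref_params, [DoseEvent(0.0, 700.0), DoseEvent(28.0, 700.0)], grid)
    one_a = pk_concentration(grid, 700.0, ref_params.ka, ref_params.cl_f,
                             ref_params.v2_f, ref_params.v3_f, ref_params.q_f)
    one_b = pk_concentration(grid, 700.0, ref_params.ka, ref_params.cl_f,
                             ref_params.v2_f, ref_params.v3_f, ref_params.q_f,
                             t_dose=28.0)
    assert np.allclose(two.drug_conc, one_a + one_b, rtol=1e-6, atol=1e-9)
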