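import math

import numpy as np
import pandas as pd
import pytest

from il13pkpd import (
    PopulationModel,
    ResidualModel,
    TrialDataset,
    TrialDesign,
    bootstrap,
    fit_pd,
    fit_pk,
    generate_trial,
    lrt_covariate,
)
from il13pkpd.estimation import FitResult
from il13pkpd.units import mg_to_nmol


def _true_pk_forcing(truth: pd.DataFrame, pop) -> FitResult:
    """A PK-stage stand-in whose EBEs are the generating individual
    parameters, to exercise the PD stage in isolation."""
    rows = []
    for _, r in truth.iterrows():
        if r["DOSE"] > 0:
            rows.append({"ID": int(r["ID"]), "ADA": int(r["ADA"]),
                         "dose_nmol": mg_to_nmol(r["DOSE"]),
                         "ka": r["ka"], "cl_f": r["cl_f"], "v2_f": r["v2_f"],
                         "v3_f": r["v3_f"], "q_f": r["q_f"]})
    return FitResult(population=pop, individual=pd.DataFrame(rows),
                     ofv=0.0, converged=True, stage="pk")


@pytest.fixture(scope="module")
def small_noisefree(small_design, noisefree_model):
    """Small trial at typical values: no IIV, near-zero noise."""
    lownoise = PopulationModel(
        typical=noisefree_model.typical,
        iiv_omega2={},
        residual=ResidualModel(pk_prop_sd=1e-4, pk_add_sd_ug_l=1e-6,
                               pd_prop_sd=1e-5),
    )
    return generate_trial(small_design, lownoise, seed=11), lownoise


class TestFitPK:
    def test_noisefree_identifiability(self, small_noisefree):
        # With etas and residual noise switched off the PK typical values
        # are recovered from generic starting values to ~1%.
        (ds, truth), pop = small_noisefree
        fit = fit_pk(ds)
        t = fit.population.typical
        for name, true in (("ka", 0.156), ("cl_f", 0.441), ("v2_f", 2.83),
                           ("v3_f", 8.03), ("q_f", 0.825)):
            assert getattr(t, name) == pytest.approx(true, rel=0.01), name
        assert fit.converged

    def test_subject_order_permutation_invariant(self, small_noisefree,
                                                 ref_model):
        (ds, _), _ = small_noisefree
        shuffled = TrialDataset(
            records=ds.records.sort_values(
                ["ID", "TIME"], ascending=[False, True]).reset_index(drop=True))
        a = fit_pk(ds, init=ref_model, max_iter=8)
        b = fit_pk(shuffled, init=ref_model, max_iter=8)
        assert a.ofv == pytest.approx(b.ofv, abs=1e-6)
        assert a.population.typical.cl_f == pytest.approx(
            b.population.typical.cl_f, rel=1e-8)

    def test_ofv_decreases_over_iterations(self, small_noisefree, ref_model):
        (ds, _), _ = small_noisefree
        fit = fit_pk(ds, init=ref_model, max_iter=10)
        trace = np.asarray(fit.trace)
        assert trace[-1] <= trace[0] + 1e-6
        # monotone within small Monte-Carlo-free jitter
        assert np.all(np.diff(trace) < 1.0)

    def test_report_table_contains_estimates(self, small_noisefree, ref_model):
        (ds, _), _ = small_noisefree
        fit = fit_pk(ds, init=ref_model, max_iter=5)
        rep = fit.report().set_index("parameter")["estimate"]
        assert {"ka", "cl_f", "v2_f", "ofv"} <= set(rep.index)


class TestFitPD:
    @pytest.mark.parametrize("fr_true, check", [
        (1e-6, lambda fr: fr <= 0.005),        # free-assay limit
        (0.9, lambda fr: fr > 0.5),            # near-total-assay limit
    ])
    def test_assay_limit_recovery(self, small_design, ref_params, fr_true,
                                  check):
        pop = PopulationModel(
            typical=ref_params.with_(fr=max(fr_true, 1e-6), ada_cl_effect=0.0),
            iiv_omega2={},
            residual=ResidualModel(pk_prop_sd=0.05, pk_add_sd_ug_l=0.01,
                                   pd_prop_sd=0.05),
        )
        ds, truth = generate_trial(small_design, pop, seed=21)
        fit = fit_pd(ds, _true_pk_forcing(truth, pop), max_iter=8)
        assert check(fit.population.typical.fr)

    def test_active_subject_without_pk_fit_rejected(self, small_design,
                                                    ref_model):
        ds, _ = generate_trial(small_design, ref_model, seed=3)
        with pytest.raises(ValueError, match="PK fit"):
            fit_pd(ds, None, init=ref_model, max_iter=2)


class TestLRT:
    def _fit(self, ofv):
        return FitResult(population=None, individual=None, ofv=ofv)

    def test_threshold_384_at_df1(self):
        assert lrt_covariate(self._fit(100.0), self._fit(103.85)).significant
        assert not lrt_covariate(self._fit(100.0), self._fit(103.83)).significant

    def test_zero_delta_not_significant(self):
        r = lrt_covariate(self._fit(50.0), self._fit(50.0))
        assert not r.significant and r.p_value == pytest.approx(1.0)

    def test_negative_delta_flagged_as_failure(self):
        r = lrt_covariate(self._fit(50.0), self._fit(40.0))
        assert r.decision == "fit_failure"
        assert math.isnan(r.p_value)

    def test_ada_effect_detected_on_synthetic_data(self, ref_model,
                                                   small_noisefree):
        # simulate with a real ADA effect, moderate noise; the nested test
        # should flag the covariate
        design = TrialDesign(cohorts=((105.0, 4), (600.0, 4)), placebo_n=0,
                             ada_prob_active=0.5)
        pop = PopulationModel(
            typical=ref_model.typical,
            iiv_omega2={"cl_f": 0.04, "v2_f": 0.04, "v3_f": 0.04, "q_f": 0.04},
            residual=ResidualModel(pk_prop_sd=0.05, pk_add_sd_ug_l=0.01),
        )
        ds, truth = generate_trial(design, pop, seed=17)
        if truth["ADA"].nunique() < 2:
            pytest.skip("degenerate ADA draw")
        with_ada = fit_pk(ds, init=pop, max_iter=12, estimate_ada=True)
        without = fit_pk(ds, init=pop, max_iter=12, estimate_ada=False)
        r = lrt_covariate(with_ada, without)
        assert r.significant


class TestBootstrap:
    def test_noisefree_gives_narrow_intervals(self, small_noisefree):
        (ds, _), pop = small_noisefree
        res = bootstrap(ds, n_reps=3, seed=1, init=pop, max_iter=6)
        assert res.n_requested == 3 and res.n_failed == 0
        lo, hi = res.ci95.loc[0.025, "cl_f"], res.ci95.loc[0.975, "cl_f"]
        assert hi - lo < 0.05 * 0.441
        assert not res.flagged

    def test_single_replicate_degenerate_interval(self, small_noisefree):
        (ds, _), pop = small_noisefree
        res = bootstrap(ds, n_reps=1, seed=2, init=pop, max_iter=4)
        assert len(res.estimates) == 1
        assert res.ci95.loc[0.025, "cl_f"] == res.ci95.loc[0.975, "cl_f"]

    def test_invalid_reps_rejected(self, small_noisefree):
        (ds, _), pop = small_noisefree
        with pytest.raises(ValueError):
            bootstrap(ds, n_reps=0, seed=1, init=pop)
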