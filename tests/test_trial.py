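import io
import math

import numpy as np
import pytest

from il13pkpd import (
    TrialDataset,
    corrupt_swap,
    default_design,
    generate_trial,
)


@pytest.fixture(scope="module")
def trial(ref_model):
    return generate_trial(default_design(), ref_model, seed=123)


class TestDesign:
    def test_arm_sizes(self):
        d = default_design()
        assert d.n_active == 24
        assert d.placebo_n == 8
        assert d.n_total == 32

    def test_expected_ada_positive_count(self):
        d = default_design()
        assert d.ada_prob_active * d.n_active == pytest.approx(16.0)

    def test_sampling_days_within_followup(self):
        d = default_design()
        assert max(d.pk_days) <= 281 and max(d.pd_days) <= 281
        assert len(d.pk_days) == 14 and len(d.pd_days) == 15


class TestGeneration:
    def test_record_counts_match_design(self, trial):
        ds, truth = trial
        assert len(truth) == 32
        assert len(ds.doses()) == 24
        assert len(ds.observations(1)) == 24 * 14
        assert len(ds.observations(2)) == 32 * 15
        for sid in ds.subject_ids:
            sub = ds.subject(sid)
            n_dose = (sub["EVID"] == 1).sum()
            assert n_dose == (1 if sub["DOSE"].iloc[0] > 0 else 0)
            # dose precedes every post-dose observation
            if n_dose:
                assert sub[sub["EVID"] == 1]["TIME"].iloc[0] == 0.0

    def test_same_seed_byte_identical(self, ref_model):
        a, _ = generate_trial(default_design(), ref_model, seed=7)
        b, _ = generate_trial(default_design(), ref_model, seed=7)
        assert a == b
        c, _ = generate_trial(default_design(), ref_model, seed=8)
        assert not (a == c)

    def test_no_variability_limit_identical_within_cohort(self, noisefree_model):
        ds, truth = generate_trial(default_design(), noisefree_model, seed=5)
        pk = ds.observations(1).merge(
            ds.doses()[["ID", "DOSE"]], on="ID", suffixes=("", "_d"))
        for dose, grp in pk.groupby("DOSE"):
            ref = grp[grp["ID"] == grp["ID"].min()].set_index("TIME")["DV"]
            for sid, sub in grp.groupby("ID"):
                got = sub.set_index("TIME")["DV"]
                assert np.allclose(got.values, ref.loc[got.index].values,
                                   rtol=1e-5)

    def test_placebo_baseline_records(self, ref_model, noisefree_model):
        ds, truth = generate_trial(default_design(), noisefree_model, seed=5)
        placebo_ids = truth.loc[truth["DOSE"] == 0, "ID"]
        pdo = ds.observations(2)
        vals = pdo[pdo["ID"].isin(placebo_ids)]["DV"]
        expected = math.log(noisefree_model.typical.baseline)
        assert np.allclose(vals, expected, rtol=1e-6)

    def test_ada_frequency_converges_to_design(self, ref_model):
        rates = []
        for seed in range(12):
            _, truth = generate_trial(default_design(), ref_model, seed=seed)
            active = truth[truth["DOSE"] > 0]
            rates.append(active["ADA"].mean())
        # binomial(24, 2/3) mean over 12 trials: SE ~ 0.028
        assert np.mean(rates) == pytest.approx(2.0 / 3.0, abs=0.09)

    def test_truth_parameters_are_lognormal_around_typical(self, trial,
                                                           ref_model):
        _, truth = trial
        eta = np.log(truth["cl_f"] / ref_model.typical.cl_f)
        eta = eta - np.log(1.717) * truth["ADA"]
        sd_expected = math.sqrt(ref_model.omega2("cl_f"))
        assert abs(eta.mean()) < 3 * sd_expected / math.sqrt(len(eta))


class TestIO:
    def test_csv_round_trip_lossless(self, trial, tmp_path):
        ds, _ = trial
        path = tmp_path / "trial.csv"
        ds.to_csv(path)
        back = TrialDataset.from_csv(path)
        assert back == ds
        text = path.read_text()
        assert text.splitlines()[0].startswith("ID,TIME,AMT,EVID")
        assert "." in text.splitlines()[1]

    def test_truth_round_trip(self, trial, tmp_path):
        _, truth = trial
        p = tmp_path / "truth.csv"
        truth.to_csv(p, index=False)
        import pandas as pd
        back = pd.read_csv(p)
        for col in ("cl_f", "fr", "kout"):
            assert np.allclose(back[col], truth[col])


class TestCorruptSwap:
    def test_swap_is_an_involution(self, trial):
        ds, _ = trial
        ids = ds.subject_ids
        once = corrupt_swap(ds, ids[0], ids[-1])
        assert not (once == ds)
        twice = corrupt_swap(once, ids[0], ids[-1])
        assert twice == ds

    def test_swapped_placebo_shows_drug_like_pd_rise(self, trial):
        ds, truth = trial
        hi = truth.loc[truth["DOSE"] == 600, "ID"].iloc[0]
        plc = truth.loc[truth["DOSE"] == 0, "ID"].iloc[0]
        swapped = corrupt_swap(ds, hi, plc)
        pdo = swapped.observations(2)
        plc_series = pdo[pdo["ID"] == plc].sort_values("TIME")["DV"].to_numpy()
        # rises by orders of magnitude on the log scale
        assert plc_series.max() - plc_series[0] > 2.0

    def test_identical_ids_rejected(self, trial):
        ds, _ = trial
        with pytest.raises(ValueError):
            corrupt_swap(ds, 1, 1)


def test_reference_fixture_consistency(ref_model, ref_params):
    from il13pkpd import reference_ci95
    assert ref_params.cl_f == 0.441
    assert ref_params.fr == 0.0429
    assert reference_ci95("cl_f") == (0.366, 0.587)
    assert reference_ci95("fr") == (0.0298, 0.0596)
    assert ref_model.omega2("cl_f") == pytest.approx(0.25006, rel=1e-3)


def test_model_serialization_round_trip(ref_model, tmp_path):
    from il13pkpd import model_from_file, model_to_file
    path = tmp_path / "model.json"
    model_to_file(ref_model, path)
    back = model_from_file(path)
    assert back.typical == ref_model.typical
    for k, v in ref_model.iiv_omega2.items():
        assert back.omega2(k) == pytest.approx(v, rel=1e-9)
    assert back.residual == ref_model.residual


def test_lloq_censoring_hook(ref_model):
    import dataclasses
    from il13pkpd import TrialDesign
    design = TrialDesign(cohorts=((105.0, 2),), placebo_n=1, lloq_pk_nm=0.5)
    ds, _ = generate_trial(design, ref_model, seed=2)
    rec = ds.records
    blq = rec[(rec["DVID"] == 1) & (rec["MDV"] == 1)]
    kept = rec[(rec["DVID"] == 1) & (rec["MDV"] == 0)]
    assert len(blq) > 0 and blq["DV"].isna().all()
    assert (kept["DV"] >= 0.5).all()
    # default design: no censoring
    ds2, _ = generate_trial(TrialDesign(cohorts=((105.0, 2),), placebo_n=1),
                            ref_model, seed=2)
    assert (ds2.records.loc[ds2.records["EVID"] == 0, "MDV"] == 0).all()
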