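"""Synthetic single-ascending-dose trial generation.

Emulates the design of the MEDI7836 first-in-human study: four active
cohorts of 6 subjects at 30/105/300/600 mg SC plus 8 placebo subjects,
followed for 281 days with rich early sampling and sparse follow-up
(about 14 PK samples per active subject and 15 PD samples per subject).
Covariates (weight, age, race) are drawn from distributions matched to the
study's baseline table; persistent post-baseline ADA positivity — the one
covariate in the final model — occurs with probability 2/3 in active
subjects and 1/8 on placebo.

Datasets use a NONMEM-style rectangular layout with columns
ID, TIME, AMT, EVID, CMT, DV, DVID (1=PK in nM, 2=PD as log nM), MDV,
DOSE (mg), ADA, ADAB, WT, AGE, RACE; missing values are written as ".".
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model_core import DoseEvent, simulate_subject
from .population import (
    PopulationModel,
    SubjectCovariates,
    draw_individual,
    pd_residual,
    pk_residual,
)
from .units import mg_to_nmol

__all__ = [
    "TrialDesign",
    "TrialDataset",
    "default_design",
    "generate_trial",
    "corrupt_swap",
]

logger = logging.getLogger(__name__)

COLUMNS = ["ID", "TIME", "AMT", "EVID", "CMT", "DV", "DVID", "MDV",
           "DOSE", "ADA", "ADAB", "WT", "AGE", "RACE"]

#: return visits printed in the protocol plus the 4-day inpatient window
PD_DAYS = (0.0, 1.0, 3.0, 6.0, 8.0, 10.0, 15.0, 29.0, 43.0, 57.0, 85.0,
           113.0, 169.0, 225.0, 281.0)
PK_DAYS = (1.0, 2.0, 3.0, 6.0, 8.0, 10.0, 15.0, 29.0, 43.0, 57.0, 85.0,
           113.0, 169.0, 225.0)


@dataclass(frozen=True)
class TrialDesign:
    """Arm structure, sampling days and covariate distributions."""

    cohorts: tuple = ((30.0, 6), (105.0, 6), (300.0, 6), (600.0, 6))
    placebo_n: int = 8
    pk_days: tuple = PK_DAYS
    pd_days: tuple = PD_DAYS
    ada_prob_active: float = 2.0 / 3.0
    ada_prob_placebo: float = 0.125
    ada_baseline_prob_active: float = 0.5
    ada_baseline_prob_placebo: float = 0.25
    weight_median: float = 76.5
    weight_log_sd: float = 0.337          # matches the printed IQR (60.4, 95.2)
    age_range: tuple = (18, 50)
    race_freqs: tuple = (("white", 0.594), ("black", 0.250), ("asian", 0.156))
    horizon: float = 281.0
    #: assay lower limits of quantification in nM; None (the default, as in
    #: the source study where no BLQ records were reported) disables
    #: censoring.  Censored observations keep their row with DV missing and
    #: MDV=1.
    lloq_pk_nm: float | None = None
    lloq_pd_nm: float | None = None

    def __post_init__(self) -> None:
        for days in (self.pk_days, self.pd_days):
            if list(days) != sorted(days) or min(days) < 0 or max(days) > self.horizon:
                raise ValueError("sampling days must be sorted within [0, horizon]")
        if any(n <= 0 for _, n in self.cohorts) or self.placebo_n < 0:
            raise ValueError("cohort sizes must be positive")

    @property
    def n_active(self) -> int:
        return sum(n for _, n in self.cohorts)

    @property
    def n_total(self) -> int:
        return self.n_active + self.placebo_n


def default_design() -> TrialDesign:
    """The default single-ascending-dose design (32 subjects)."""
    return TrialDesign()


@dataclass
class TrialDataset:
    """Rectangular dosing/observation records for one (synthetic) trial."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.records = self.records.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["ID"].unique()

    def subject(self, sid) -> pd.DataFrame:
        return self.records[self.records["ID"] == sid]

    def observations(self, dvid: int) -> pd.DataFrame:
        r = self.records
        return r[(r["EVID"] == 0) & (r["DVID"] == dvid) & (r["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        df = self.records.copy()
        for col in df.columns:
            if col == "RACE":
                continue
            df[col] = df[col].map(
                lambda v: "." if pd.isna(v) else format(float(v), ".10g"))
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialDataset":
        df = pd.read_csv(path_or_buf, na_values=["."], dtype={"RACE": str})
        for col in df.columns:
            if col != "RACE":
                df[col] = pd.to_numeric(df[col])
        for col in ("ID", "EVID", "CMT", "DVID", "MDV", "ADA", "ADAB"):
            df[col] = df[col].fillna(-1).astype(int).replace(-1, np.nan)
        return cls(records=df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        a, b = io.StringIO(), io.StringIO()
        self.to_csv(a)
        other.to_csv(b)
        return a.getvalue() == b.getvalue()


def _draw_covariates(design: TrialDesign, active: bool,
                     rng: np.random.Generator) -> SubjectCovariates:
    w = float(design.weight_median * math.exp(
        rng.normal(0.0, design.weight_log_sd)))
    age = int(rng.integers(design.age_range[0], design.age_range[1] + 1))
    names, probs = zip(*design.race_freqs)
    probs = np.asarray(probs) / sum(probs)
    race = str(rng.choice(names, p=probs))
    p_ada = design.ada_prob_active if active else design.ada_prob_placebo
    p_adab = (design.ada_baseline_prob_active if active
              else design.ada_baseline_prob_placebo)
    return SubjectCovariates(
        weight=w, age=age, race=race,
        ada_status=int(rng.random() < p_ada),
        ada_baseline=int(rng.random() < p_adab),
    )


def generate_trial(design: TrialDesign, pop: PopulationModel, seed: int,
                   max_regen: int = 5):
    """Forward-simulate one trial; returns ``(TrialDataset, truth)``.

    ``truth`` is a per-subject DataFrame with the generating individual
    parameters and etas, for recovery testing.  The same seed always yields
    a byte-identical dataset.
    """
    rng = np.random.default_rng(seed)
    rows: list = []
    truth_rows: list = []
    sid = 0
    arms = [(mg, n) for mg, n in design.cohorts] + [(0.0, design.placebo_n)]
    obs_grid = np.unique(np.concatenate(
        [[0.0], design.pk_days, design.pd_days, [design.horizon]]))
    for dose_mg, n_sub in arms:
        active = dose_mg > 0
        for _ in range(n_sub):
            sid += 1
            for attempt in range(max_regen):
                cov = _draw_covariates(design, active, rng)
                ind = draw_individual(pop, cov, rng)
                p = ind.params
                try:
                    rows_i = _simulate_records(
                        sid, dose_mg, active, cov, p, design, obs_grid, pop, rng)
                except ValueError as err:   # non-positive detected IL13
                    logger.warning("regenerating subject %d: %s", sid, err)
                    continue
                break
            else:
                raise RuntimeError(f"subject {sid} failed after {max_regen} draws")
            rows.extend(rows_i)
            tr = {"ID": sid, "DOSE": dose_mg, "ADA": cov.ada_status,
                  "ADAB": cov.ada_baseline, "WT": cov.weight, "AGE": cov.age,
                  "RACE": cov.race}
            tr.update({k: getattr(p, k) for k in
                       ("ka", "cl_f", "v2_f", "v3_f", "q_f", "kin", "kout",
                        "vcx_f", "fr")})
            tr.update({f"eta_{k}": v for k, v in ind.eta.items()})
            truth_rows.append(tr)
    df = pd.DataFrame(rows, columns=COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return TrialDataset(records=df), truth


def _simulate_records(sid, dose_mg, active, cov, p, design, obs_grid, pop, rng):
    """Rows for one subject; raises ValueError if detected IL13 is not positive."""
    base = {"ID": sid, "DOSE": dose_mg, "ADA": cov.ada_status,
            "ADAB": cov.ada_baseline, "WT": round(cov.weight, 2),
            "AGE": cov.age, "RACE": cov.race}
    rows = []
    if active:
        # ADA multiplier is already folded into the individual cl_f
        traj = simulate_subject(p, [DoseEvent(0.0, mg_to_nmol(dose_mg))], obs_grid)
        free = dict(zip(obs_grid, traj.free_il13))
        ccx = dict(zip(obs_grid, traj.complex_conc))
        drug = dict(zip(obs_grid, traj.drug_conc))
        rows.append({**base, "TIME": 0.0, "AMT": mg_to_nmol(dose_mg),
                     "EVID": 1, "CMT": 1, "DV": np.nan, "DVID": np.nan, "MDV": 1})
    else:
        b = p.baseline
        free = {t: b for t in obs_grid}
        ccx = {t: 0.0 for t in obs_grid}
        drug = {t: 0.0 for t in obs_grid}

    if active:
        for t in design.pk_days:
            eps1 = rng.normal(0.0, pop.residual.pk_prop_sd)
            eps2 = rng.normal(0.0, pop.residual.pk_add_sd_ug_l)
            y = pk_residual(max(drug[t], 0.0), eps1, eps2, pop.units)
            blq = design.lloq_pk_nm is not None and y < design.lloq_pk_nm
            rows.append({**base, "TIME": t, "AMT": np.nan, "EVID": 0, "CMT": 2,
                         "DV": np.nan if blq else y, "DVID": 1,
                         "MDV": 1 if blq else 0})
    for t in design.pd_days:
        det_free = max(free[t], 0.0)
        det_cx = max(ccx[t], 0.0)
        if det_free + p.fr * det_cx <= 0:
            raise ValueError(f"non-positive detected IL13 at t={t}")
        eps3 = rng.normal(0.0, pop.residual.pd_prop_sd)
        y = pd_residual(det_free, det_cx, p.fr, eps3)
        blq = (design.lloq_pd_nm is not None
               and math.exp(y) < design.lloq_pd_nm)
        rows.append({**base, "TIME": t, "AMT": np.nan, "EVID": 0, "CMT": 4,
                     "DV": np.nan if blq else y, "DVID": 2,
                     "MDV": 1 if blq else 0})
    return rows


def corrupt_swap(data: TrialDataset, subject_a, subject_b) -> TrialDataset:
    """Exchange the PD series of two subjects (sample-swap corruption).

    Mirrors the kind of handling error suspected in the source study, where
    a placebo subject showed a drug-like IL13 profile; useful for exercising
    outlier-exclusion workflows.  Returns a new dataset.
    """
    if subject_a == subject_b:
        raise ValueError("subjects to swap must differ")
    df = data.records.copy()
    mask_a = (df["ID"] == subject_a) & (df["DVID"] == 2) & (df["EVID"] == 0)
    mask_b = (df["ID"] == subject_b) & (df["DVID"] == 2) & (df["EVID"] == 0)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both subjects must exist and carry PD records")
    if mask_a.sum() != mask_b.sum():
        raise ValueError("subjects have different numbers of PD records")
    dv_a = df.loc[mask_a, "DV"].to_numpy()
    df.loc[mask_a, "DV"] = df.loc[mask_b, "DV"].to_numpy()
    df.loc[mask_b, "DV"] = dv_a
    return TrialDataset(records=df)
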