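"""Population layer: inter-individual variability, covariates, residual error.

Parameters with IIV follow the usual log-normal convention
``theta_i = TV * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)``; the typical
value is therefore the population median.  The final covariate model carries
a single effect, the fractional clearance increase for subjects who are
persistently ADA-positive after baseline.

Residual error:

* PK (drug concentration, nM): combined proportional + additive,
  ``y = f * (1 + eps1) + eps2`` with the additive SD specified on the
  assay's ug/L mass scale and converted to nM internally.
* PD (log of detected IL13, natural log of nM): proportional on the log
  scale, ``y = log(free + FR * Cx) * (1 + eps3)``.  This follows the source
  model's observation equation verbatim; note it makes the error SD scale
  with the magnitude of the log-prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .model_core import StructuralParams
from .units import UnitConventions, ug_per_l_to_nm

__all__ = [
    "PK_IIV_PARAMS",
    "PD_IIV_PARAMS",
    "ResidualModel",
    "PopulationModel",
    "SubjectCovariates",
    "IndividualParams",
    "apply_iiv",
    "apply_covariates",
    "draw_individual",
    "cv_from_omega2",
    "omega2_from_cv",
    "pk_residual",
    "pd_residual",
]

logger = logging.getLogger(__name__)

PK_IIV_PARAMS = ("cl_f", "v2_f", "v3_f", "q_f")
PD_IIV_PARAMS = ("kout", "fr")


def cv_from_omega2(omega2: float) -> float:
    """Percent CV of a log-normal variate with log-variance ``omega2``.

    CV% = 100 * sqrt(exp(omega2) - 1).
    """
    if omega2 < 0:
        raise ValueError(f"variance omega2={omega2!r} must be non-negative")
    return 100.0 * math.sqrt(math.expm1(omega2))


def omega2_from_cv(cv_percent: float) -> float:
    """Inverse of :func:`cv_from_omega2`: omega2 = log(1 + (CV/100)^2)."""
    if cv_percent < 0:
        raise ValueError("CV must be non-negative")
    return math.log1p((cv_percent / 100.0) ** 2)


@dataclass(frozen=True)
class ResidualModel:
    """Residual (within-subject) error magnitudes.

    pk_prop_sd: proportional SD of the PK error (dimensionless).
    pk_add_sd_ug_l: additive SD of the PK error on the ug/L mass scale.
    pd_prop_sd: proportional SD applied to the log-scale PD prediction.
    """

    pk_prop_sd: float = 0.13
    pk_add_sd_ug_l: float = 0.0546
    pd_prop_sd: float = 0.069

    def __post_init__(self) -> None:
        if min(self.pk_prop_sd, self.pk_add_sd_ug_l, self.pd_prop_sd) < 0:
            raise ValueError("residual SDs must be non-negative")

    def pk_add_sd_nm(self, units: UnitConventions) -> float:
        return ug_per_l_to_nm(self.pk_add_sd_ug_l, units.mw_drug)


@dataclass
class PopulationModel:
    """Typical values, IIV variances, covariate effect and residual error."""

    typical: StructuralParams
    iiv_omega2: dict = field(default_factory=dict)
    residual: ResidualModel = field(default_factory=ResidualModel)
    units: UnitConventions = field(default_factory=UnitConventions)
    #: optional correlation matrix for the PK etas (order PK_IIV_PARAMS);
    #: None means independent random effects (the default model).
    pk_eta_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        for k, v in self.iiv_omega2.items():
            if v < 0:
                raise ValueError(f"iiv_omega2[{k!r}] must be non-negative")
        if self.pk_eta_corr is not None:
            c = np.asarray(self.pk_eta_corr, dtype=float)
            if c.shape != (len(PK_IIV_PARAMS),) * 2 or not np.allclose(c, c.T):
                raise ValueError("pk_eta_corr must be a symmetric 4x4 matrix")
            self.pk_eta_corr = c

    def omega2(self, name: str) -> float:
        return float(self.iiv_omega2.get(name, 0.0))

    def iiv_cv_percent(self) -> dict:
        return {k: cv_from_omega2(v) for k, v in self.iiv_omega2.items()}

    def replace_typical(self, **kwargs) -> "PopulationModel":
        return replace(self, typical=self.typical.with_(**kwargs))


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates; ``ada_status`` is 1 for persistent post-baseline
    ADA positivity (the only covariate in the final model)."""

    weight: float = 76.5
    age: float = 35.0
    race: str = "white"
    ada_status: int = 0
    ada_baseline: int = 0

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.age <= 0:
            raise ValueError("weight and age must be positive")
        if self.ada_status not in (0, 1) or self.ada_baseline not in (0, 1):
            raise ValueError("ADA indicators must be 0/1")


@dataclass
class IndividualParams:
    """Structural parameters after IIV and covariates, with their etas."""

    params: StructuralParams
    eta: dict = field(default_factory=dict)
    covariates: SubjectCovariates | None = None


def apply_iiv(pop: PopulationModel, eta: Mapping[str, float]) -> IndividualParams:
    """Apply log-normal random effects: affected parameters x exp(eta)."""
    updates = {}
    for name, e in eta.items():
        if pop.omega2(name) <= 0.0:
            raise ValueError(
                f"eta supplied for {name!r}, which has no declared IIV variance")
        updates[name] = getattr(pop.typical, name) * math.exp(e)
    ind = pop.typical.with_(**updates) if updates else pop.typical
    return IndividualParams(params=ind, eta=dict(eta))


def apply_covariates(ind: IndividualParams, cov: SubjectCovariates,
                     pop: PopulationModel) -> IndividualParams:
    """Apply the covariate model (ADA -> clearance in the final model).

    Discrete covariates multiply the parameter by ``1 + theta_cov`` for the
    non-reference category; continuous covariates (none retained in the
    final model) would multiply by ``1 + theta_cov * (cov - median)``.
    """
    p = ind.params
    if cov.ada_status == 1:
        mult = 1.0 + p.ada_cl_effect
        if mult <= 0:
            raise ValueError("ADA covariate multiplier must keep CL positive")
        p = p.with_(cl_f=p.cl_f * mult)
    return IndividualParams(params=p, eta=dict(ind.eta), covariates=cov)


def draw_individual(pop: PopulationModel, cov: SubjectCovariates,
                    rng: np.random.Generator) -> IndividualParams:
    """Draw one subject's parameters: etas, then covariates.

    The detected-complex fraction is capped at 1 (its log-normal IIV is wide
    enough — 154 %CV — that ~0.2% of draws would otherwise exceed a physical
    fraction); capped draws are logged.
    """
    eta: dict = {}
    pk_names = [n for n in PK_IIV_PARAMS if pop.omega2(n) > 0]
    if pk_names and pop.pk_eta_corr is not None:
        sd = np.array([math.sqrt(pop.omega2(n)) for n in PK_IIV_PARAMS])
        cov_m = pop.pk_eta_corr * np.outer(sd, sd)
        draw = rng.multivariate_normal(np.zeros(len(PK_IIV_PARAMS)), cov_m)
        eta.update({n: float(d) for n, d in zip(PK_IIV_PARAMS, draw)
                    if pop.omega2(n) > 0})
    else:
        for n in pk_names:
            eta[n] = float(rng.normal(0.0, math.sqrt(pop.omega2(n))))
    for n in PD_IIV_PARAMS:
        if pop.omega2(n) > 0:
            eta[n] = float(rng.normal(0.0, math.sqrt(pop.omega2(n))))
    if "fr" in eta and pop.typical.fr > 0:
        eta_cap = math.log(1.0 / pop.typical.fr)
        if eta["fr"] > eta_cap:
            logger.info("capping FR eta %.3f at %.3f (FR=1)", eta["fr"], eta_cap)
            eta["fr"] = eta_cap
    ind = apply_iiv(pop, eta)
    return apply_covariates(ind, cov, pop)


def pk_residual(pred_nm, eps_prop, eps_add_ugl,
                units: UnitConventions = UnitConventions()):
    """Combined residual error on a PK prediction (all nM in/out).

    ``y = f * (1 + eps_prop) + eps_add`` with the additive draw supplied on
    the ug/L scale.  Negative simulated observations are floored at zero
    (count logged), mirroring how a concentration assay reports.
    """
    pred = np.asarray(pred_nm, dtype=float)
    if np.any(pred < 0):
        raise ValueError("PK predictions must be non-negative")
    y = pred * (1.0 + np.asarray(eps_prop)) + ug_per_l_to_nm(
        np.asarray(eps_add_ugl), units.mw_drug)
    n_neg = int(np.sum(y < 0))
    if n_neg:
        logger.info("flooring %d negative simulated PK observations at 0", n_neg)
    y = np.maximum(y, 0.0)
    return y if y.ndim else float(y)


def pd_residual(free_nm, cx_nm, fr: float, eps3):
    """Log-scale proportional residual on the detected-IL13 prediction.

    Returns ``log(free + fr*cx) * (1 + eps3)`` (natural log of nM).
    """
    det = np.asarray(free_nm, dtype=float) + fr * np.asarray(cx_nm, dtype=float)
    if np.any(det <= 0):
        raise ValueError("detected IL13 must be positive to take its log")
    y = np.log(det) * (1.0 + np.asarray(eps3))
    return y if y.ndim else float(y)
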