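"""Bundled reference parameter set (MEDI7836 final model estimates)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .model_core import StructuralParams
from .population import (PopulationModel, ResidualModel, cv_from_omega2,
                         omega2_from_cv)

__all__ = ["load_reference", "model_from_file", "model_to_file",
           "reference_params", "reference_model", "reference_ci95"]


@lru_cache(maxsize=1)
def load_reference() -> dict:
    """Raw reference parameter file (values, units, bootstrap CIs)."""
    with resources.files("il13pkpd.data").joinpath(
            "medi7836_reference.json").open() as fh:
        return json.load(fh)


def model_from_file(path) -> PopulationModel:
    """Load a population model from a parameter file in the same key-value
    JSON layout as the bundled reference set."""
    with open(path) as fh:
        ref = json.load(fh)
    typical = StructuralParams(
        **{k: v["value"] for k, v in ref["structural"].items()})
    iiv = {k: omega2_from_cv(v["value"])
           for k, v in ref.get("iiv_cv_percent", {}).items()}
    res = ResidualModel(
        **{k: v["value"] for k, v in ref.get("residual", {}).items()})
    return PopulationModel(typical=typical, iiv_omega2=iiv, residual=res)


def reference_params() -> StructuralParams:
    """Typical structural parameters of the final model."""
    s = load_reference()["structural"]
    return StructuralParams(**{k: v["value"] for k, v in s.items()})


def reference_model() -> PopulationModel:
    """Full population model: typical values, IIV, residual error."""
    ref = load_reference()
    iiv = {k: omega2_from_cv(v["value"]) for k, v in ref["iiv_cv_percent"].items()}
    res = ResidualModel(**{k: v["value"] for k, v in ref["residual"].items()})
    return PopulationModel(typical=reference_params(), iiv_omega2=iiv, residual=res)


def model_to_file(pop: PopulationModel, path) -> None:
    """Write a population model in the reference key-value JSON layout
    (structural values, IIV as %CV, residual SDs); inverse of
    :func:`model_from_file`."""
    t = pop.typical
    doc = {
        "structural": {k: {"value": getattr(t, k)} for k in (
            "ka", "cl_f", "v2_f", "v3_f", "q_f", "kin", "kout", "kon",
            "koff", "vcx_f", "fr", "ada_cl_effect")},
        "iiv_cv_percent": {k: {"value": cv_from_omega2(v)}
                           for k, v in pop.iiv_omega2.items()},
        "residual": {
            "pk_prop_sd": {"value": pop.residual.pk_prop_sd},
            "pk_add_sd_ug_l": {"value": pop.residual.pk_add_sd_ug_l},
            "pd_prop_sd": {"value": pop.residual.pd_prop_sd},
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def reference_ci95(name: str) -> tuple:
    """Bootstrap 95% interval for a structural parameter, as (lo, hi)."""
    entry = load_reference()["structural"][name]
    lo, hi = entry["ci95"]
    return float(lo), float(hi)
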