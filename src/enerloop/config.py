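"""Flat key-value configuration shared across modules.

All parameter objects serialize to a single flat mapping (dotted keys) in
YAML, e.g.::

    cohort.name: cushing_circadian
    cohort.gap_mean_min: 59.0
    cohort.gap_sd_min: 11.0
    cohort.amplitude.kind: harmonic
    cohort.amplitude.baseline: 38.5
    ...
    cortisol.zeta1: 0.12
    model.rho: 0.9

so a run is fully described by one human-editable file.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .actuation import MedicationModel
from .energy_model import EnergyStateModel, HarmonicCoefficients
from .virtual_patient import (
    CohortSpec,
    CortisolParams,
    FlatAmplitudeLaw,
    HarmonicAmplitudeLaw,
)

__all__ = [
    "cohort_to_config",
    "cohort_from_config",
    "cortisol_to_config",
    "cortisol_from_config",
    "model_to_config",
    "model_from_config",
    "medication_to_config",
    "medication_from_config",
    "save_config",
    "load_config",
]


def cohort_to_config(cohort: CohortSpec, prefix: str = "cohort") -> dict:
    out = {
        f"{prefix}.name": cohort.name,
        f"{prefix}.gap_mean_min": float(cohort.gap_mean_min),
        f"{prefix}.gap_sd_min": float(cohort.gap_sd_min),
    }
    law = cohort.amplitude_law
    if isinstance(law, HarmonicAmplitudeLaw):
        out[f"{prefix}.amplitude.kind"] = "harmonic"
        for name in ("baseline", "a1", "b1", "a2", "b2", "cv"):
            out[f"{prefix}.amplitude.{name}"] = float(getattr(law, name))
    else:
        out[f"{prefix}.amplitude.kind"] = "flat"
        out[f"{prefix}.amplitude.mean"] = float(law.mean)
        out[f"{prefix}.amplitude.sd"] = float(law.sd)
    return out


def cohort_from_config(cfg: dict, prefix: str = "cohort") -> CohortSpec:
    kind = cfg[f"{prefix}.amplitude.kind"]
    if kind == "harmonic":
        law = HarmonicAmplitudeLaw(
            baseline=cfg[f"{prefix}.amplitude.baseline"],
            a1=cfg[f"{prefix}.amplitude.a1"],
            b1=cfg[f"{prefix}.amplitude.b1"],
            a2=cfg[f"{prefix}.amplitude.a2"],
            b2=cfg[f"{prefix}.amplitude.b2"],
            cv=cfg[f"{prefix}.amplitude.cv"],
        )
    elif kind == "flat":
        law = FlatAmplitudeLaw(
            mean=cfg[f"{prefix}.amplitude.mean"], sd=cfg[f"{prefix}.amplitude.sd"]
        )
    else:
        raise ValueError(f"unknown amplitude law kind {kind!r}")
    return CohortSpec(
        name=cfg[f"{prefix}.name"],
        gap_mean_min=cfg[f"{prefix}.gap_mean_min"],
        gap_sd_min=cfg[f"{prefix}.gap_sd_min"],
        amplitude_law=law,
    )


def cortisol_to_config(params: CortisolParams, prefix: str = "cortisol") -> dict:
    return {
        f"{prefix}.zeta1": float(params.zeta1),
        f"{prefix}.zeta2": float(params.zeta2),
        f"{prefix}.sigma_psi2": float(params.sigma_psi2),
    }


def cortisol_from_config(cfg: dict, prefix: str = "cortisol") -> CortisolParams:
    return CortisolParams(
        zeta1=cfg[f"{prefix}.zeta1"],
        zeta2=cfg[f"{prefix}.zeta2"],
        sigma_psi2=cfg[f"{prefix}.sigma_psi2"],
    )


_MODEL_FIELDS = (
    "rho",
    "sigma_eps2",
    "gamma0",
    "gamma1",
    "r0",
    "r1",
    "sigma_v2",
    "s0",
    "s1",
    "sigma_w2",
)
_HARMONIC_FIELDS = ("alpha1", "alpha2", "beta1", "beta2")


def model_to_config(model: EnergyStateModel, prefix: str = "model") -> dict:
    out = {f"{prefix}.{k}": float(getattr(model, k)) for k in _MODEL_FIELDS}
    out.update(
        {f"{prefix}.{k}": float(getattr(model.harmonic, k)) for k in _HARMONIC_FIELDS}
    )
    return out


def model_from_config(cfg: dict, prefix: str = "model") -> EnergyStateModel:
    return EnergyStateModel(
        harmonic=HarmonicCoefficients(
            **{k: cfg[f"{prefix}.{k}"] for k in _HARMONIC_FIELDS}
        ),
        **{k: cfg[f"{prefix}.{k}"] for k in _MODEL_FIELDS},
    )


def medication_to_config(med: MedicationModel, prefix: str = "medication") -> dict:
    return {
        f"{prefix}.theta1": float(med.theta1),
        f"{prefix}.theta2": float(med.theta2),
        f"{prefix}.eta": int(med.eta),
    }


def medication_from_config(cfg: dict, prefix: str = "medication") -> MedicationModel:
    return MedicationModel(
        theta1=cfg[f"{prefix}.theta1"],
        theta2=cfg[f"{prefix}.theta2"],
        eta=cfg[f"{prefix}.eta"],
    )


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_config(path: str | Path) -> dict:
    out = yaml.safe_load(Path(path).read_text())
    if not isinstance(out, dict):
        raise ValueError(f"config file {path} does not hold a flat mapping")
    return out
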