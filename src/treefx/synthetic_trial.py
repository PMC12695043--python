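"""Synthetic two-arm trial generator with planted threshold effects.

Produces trial tables whose treatment effect on the 24-week ppFVC change
depends on two serum markers through planted cuts: a high-CRP leaf, a
low-CRP/high-KL6 leaf and a low-CRP/low-KL6 leaf, each with its own
effect and control-arm drift.  All other covariates are pure noise by
default.  Serves as ground truth for the tree and inference modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trial_data import TrialDataset, covariate_catalog

__all__ = [
    "SimulationConfig",
    "default_covariate_params",
    "sample_covariates",
    "true_tau",
    "true_leaf",
    "generate_trial",
    "inject_missing_outcomes",
]


def default_covariate_params() -> dict[str, dict]:
    """Distribution settings per catalog covariate.

    Binary: Bernoulli prevalence.  Continuous: log-normal calibrated so the
    median lands near the observed trial marginals; CRP is zero-inflated
    (point mass at 0 with probability ~0.5, else log-normal) rounded to
    2 decimals; KL-6 is rounded to integers.
    """
    p = {
        "sex_female": {"kind": "binary", "prev": 0.917},
        "prev_immunosuppressant": {"kind": "binary", "prev": 0.542},
        "dcssc": {"kind": "binary", "prev": 0.813},
        "puffy_fingers": {"kind": "binary", "prev": 0.854},
        "skin_ulcer": {"kind": "binary", "prev": 0.667},
        "reflux_esophagitis": {"kind": "binary", "prev": 0.917},
        "barrett_esophagus": {"kind": "binary", "prev": 0.146},
        "arthritis": {"kind": "binary", "prev": 0.271},
        "age": {"kind": "lognormal", "median": 48.0, "sigma": 0.22, "round": 0},
        "disease_duration": {"kind": "lognormal", "median": 76.5, "sigma": 0.9, "round": 0},
        "mrss": {"kind": "lognormal", "median": 13.5, "sigma": 0.2, "round": 0},
        "anti_topo_titre": {"kind": "lognormal", "median": 93.5, "sigma": 1.2, "round": 1},
        "anti_centromere_titre": {"kind": "lognormal", "median": 4.9, "sigma": 0.6, "round": 1},
        "anti_rnap3_titre": {"kind": "lognormal", "median": 4.9, "sigma": 0.5, "round": 1},
        "cd19_count": {"kind": "lognormal", "median": 180.0, "sigma": 0.6, "round": 0},
        "cd20_count": {"kind": "lognormal", "median": 180.0, "sigma": 0.6, "round": 0},
        "ppfvc_baseline": {"kind": "lognormal", "median": 85.8, "sigma": 0.13, "round": 1},
        "dlco": {"kind": "lognormal", "median": 79.5, "sigma": 0.2, "round": 1},
        "KL6": {"kind": "lognormal", "median": 453.5, "sigma": 0.8, "round": 0},
        "sp_a": {"kind": "lognormal", "median": 33.1, "sigma": 0.5, "round": 1},
        "sp_d": {"kind": "lognormal", "median": 141.4, "sigma": 0.6, "round": 1},
        "total_protein": {"kind": "lognormal", "median": 7.0, "sigma": 0.07, "round": 1},
        "CRP": {"kind": "zero_inflated_lognormal", "p_zero": 0.52, "median": 0.15,
                "sigma": 0.8, "round": 2},
        "igg": {"kind": "lognormal", "median": 1305.0, "sigma": 0.25, "round": 0},
        "igm": {"kind": "lognormal", "median": 114.5, "sigma": 0.5, "round": 0},
        "bnp": {"kind": "lognormal", "median": 17.4, "sigma": 0.8, "round": 1},
        "haemoglobin": {"kind": "lognormal", "median": 12.5, "sigma": 0.09, "round": 1},
        "interstitial_shadow_area": {"kind": "lognormal", "median": 11.0, "sigma": 0.9, "round": 0},
    }
    return p


@dataclass(frozen=True)
class SimulationConfig:
    """Planted-effect trial model.

    ``leaf_effects`` are the treatment effects (active minus control, in
    percentage points of ppFVC change) for the (high-CRP, low-CRP/high-KL6,
    low-CRP/low-KL6) regions; ``control_means`` the control-arm mean drifts
    in the same regions.
    """

    n: int = 48
    treat_frac: float = 25 / 48
    crp_cut: float = 0.055
    kl6_cut: float = 364.0
    leaf_effects: tuple[float, float, float] = (8.01, 2.47, -6.85)
    control_means: tuple[float, float, float] = (-6.40, -3.70, 6.12)
    noise_sd: float = 5.0
    missing_frac: float = 3 / 23
    covariate_params: Mapping[str, dict] = field(default_factory=default_covariate_params)
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.treat_frac < 1.0:
            raise ValidationError("treat_frac must be in (0,1)")
        if self.noise_sd < 0.0:
            raise ValidationError("noise_sd must be non-negative")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValidationError("missing_frac must be in [0,1)")


def sample_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw all 28 catalog covariates for cfg.n patients."""
    cols: dict[str, np.ndarray] = {}
    for spec in covariate_catalog():
        params = cfg.covariate_params[spec.name]
        kind = params["kind"]
        if kind == "binary":
            cols[spec.name] = rng.binomial(1, params["prev"], cfg.n).astype(float)
        elif kind == "lognormal":
            x = rng.lognormal(math.log(params["median"]), params["sigma"], cfg.n)
            cols[spec.name] = np.round(x, params["round"])
        elif kind == "zero_inflated_lognormal":
            zero = rng.random(cfg.n) < params["p_zero"]
            x = rng.lognormal(math.log(params["median"]), params["sigma"], cfg.n)
            x = np.round(x, params["round"])
            x[zero] = 0.0
            cols[spec.name] = x
        else:
            raise ValidationError(f"unknown covariate distribution kind {kind!r}")
    return pd.DataFrame(cols)


def true_leaf(record: Mapping[str, float], cfg: SimulationConfig) -> int:
    """Planted region of one record: 1 high-CRP, 2 high-KL6, 3 double-low."""
    for key in ("CRP", "KL6"):
        v = record.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValidationError(f"record missing {key}")
    if record["CRP"] >= cfg.crp_cut:
        return 1
    if record["KL6"] >= cfg.kl6_cut:
        return 2
    return 3


def true_tau(record: Mapping[str, float], cfg: SimulationConfig) -> float:
    """Planted treatment effect for one covariate record."""
    return cfg.leaf_effects[true_leaf(record, cfg) - 1]


def _allocate_arms(n: int, treat_frac: float, rng: np.random.Generator) -> np.ndarray:
    n1 = int(round(n * treat_frac))
    if n1 < 1 or n - n1 < 1:
        raise ValidationError(f"n={n} too small for both arms to be non-empty")
    arm = np.array([1] * n1 + [0] * (n - n1), dtype=int)
    rng.shuffle(arm)
    return arm


def generate_trial(cfg: SimulationConfig) -> TrialDataset:
    """Generate a loadable trial dataset with the planted effect model.

    Week-24 ppFVC is week-0 plus the region's control drift, plus the
    region effect for treated patients, plus Gaussian noise.  A week-12
    value is always generated with the same mean structure so that LOCF
    after missingness injection is unbiased.  Missingness is injected
    into week-24 of a ``missing_frac`` share of control patients.
    """
    rng = np.random.default_rng(cfg.seed)
    cov = sample_covariates(cfg, rng)
    arm = _allocate_arms(cfg.n, cfg.treat_frac, rng)

    leaf = np.array(
        [true_leaf({"CRP": cov["CRP"].iloc[i], "KL6": cov["KL6"].iloc[i]}, cfg)
         for i in range(cfg.n)]
    )
    tau = np.array([cfg.leaf_effects[k - 1] for k in leaf], dtype=float)
    drift = np.array([cfg.control_means[k - 1] for k in leaf], dtype=float)

    w0 = cov["ppfvc_baseline"].to_numpy(float)
    mean_change = drift + arm * tau
    w12 = w0 + mean_change + rng.normal(0.0, cfg.noise_sd, cfg.n)
    w24 = w0 + mean_change + rng.normal(0.0, cfg.noise_sd, cfg.n)

    ds = TrialDataset(
        patient_id=tuple(f"P{i + 1:04d}" for i in range(cfg.n)),
        arm=arm,
        ppfvc=pd.DataFrame({0: w0, 12: w12, 24: w24}),
        covariates=cov,
        catalog=tuple(covariate_catalog()),
    )
    if cfg.missing_frac > 0.0:
        ds = inject_missing_outcomes(ds, cfg.missing_frac, int(rng.integers(2**31)))
    return ds


def inject_missing_outcomes(ds: TrialDataset, frac: float, seed: int) -> TrialDataset:
    """Blank week-24 ppFVC for a seeded random share of control patients."""
    if not 0.0 <= frac < 1.0:
        raise ValidationError("missing fraction must be in [0,1)")
    if frac == 0.0:
        return ds
    rng = np.random.default_rng(seed)
    controls = np.nonzero(ds.arm == 0)[0]
    k = int(round(frac * len(controls)))
    if k == 0:
        return ds
    chosen = rng.choice(controls, size=k, replace=False)
    pp = ds.ppfvc.copy()
    col = pp[24].to_numpy(float).copy()
    col[chosen] = np.nan
    pp[24] = col
    return dc_replace(ds, ppfvc=pp)
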