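"""Patient-level trial table: data model, CSV I/O, outcome construction.

The table holds one row per patient with a binary arm indicator
(0 = control/placebo, 1 = active), percent-predicted FVC by visit week,
and a catalog of baseline covariates.  The derived outcome is the
absolute change in ppFVC between week 0 and a target week, computed
after last-observation-carried-forward (LOCF) imputation.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CovariateSpec",
    "TrialDataset",
    "covariate_catalog",
    "load_trial_table",
    "write_trial_table",
    "locf_impute_outcome",
    "compute_delta_ppfvc",
]

CONTINUOUS = "continuous"
BINARY = "binary"

_PPFVC_COL = re.compile(r"^ppfvc_w(\d+)$")


@dataclass(frozen=True)
class CovariateSpec:
    """Description of one baseline covariate."""

    name: str
    kind: str  # "continuous" | "binary"
    unit: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValidationError(f"unknown covariate kind {self.kind!r}")

    def admissible(self, value: float) -> bool:
        """Whether a non-missing value respects this spec's kind."""
        if self.kind == BINARY:
            return value in (0, 1)
        return math.isfinite(value)


def covariate_catalog() -> list[CovariateSpec]:
    """The default 28-covariate baseline catalog (8 binary, 20 continuous)."""
    binary = [
        ("sex_female", "female sex"),
        ("prev_immunosuppressant", "previous use of immunosuppressants/biologics"),
        ("dcssc", "diffuse cutaneous systemic sclerosis"),
        ("puffy_fingers", "puffy fingers"),
        ("skin_ulcer", "skin ulcer"),
        ("reflux_esophagitis", "reflux esophagitis"),
        ("barrett_esophagus", "Barrett's esophagus"),
        ("arthritis", "arthritis"),
    ]
    continuous = [
        ("age", "years", "age"),
        ("disease_duration", "months", "disease duration"),
        ("mrss", "", "modified Rodnan skin score"),
        ("anti_topo_titre", "U/ml", "anti-topoisomerase I antibody titre"),
        ("anti_centromere_titre", "U/ml", "anti-centromere antibody titre"),
        ("anti_rnap3_titre", "U/ml", "anti-RNA polymerase III antibody titre"),
        ("cd19_count", "cells/ul", "CD19-positive cell count"),
        ("cd20_count", "cells/ul", "CD20-positive cell count"),
        ("ppfvc_baseline", "%", "percent-predicted FVC at baseline"),
        ("dlco", "%", "percent-predicted DLco"),
        ("KL6", "U/ml", "serum KL-6"),
        ("sp_a", "ng/ml", "serum surfactant protein A"),
        ("sp_d", "ng/ml", "serum surfactant protein D"),
        ("total_protein", "g/dl", "total serum protein"),
        ("CRP", "mg/dl", "serum C-reactive protein"),
        ("igg", "mg/dl", "serum IgG"),
        ("igm", "mg/dl", "serum IgM"),
        ("bnp", "pg/ml", "serum brain natriuretic peptide"),
        ("haemoglobin", "g/dl", "haemoglobin"),
        ("interstitial_shadow_area", "% of lung", "interstitial-shadow area on HRCT"),
    ]
    specs = [CovariateSpec(n, BINARY, "", d) for n, d in binary]
    specs += [CovariateSpec(n, CONTINUOUS, u, d) for n, u, d in continuous]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):  # pragma: no cover - construction guard
        raise ValidationError("covariate names must be unique")
    return specs


@dataclass(frozen=True)
class TrialDataset:
    """Validated patient-level two-arm trial table.

    ``ppfvc`` has one column per integer visit week (ascending); NaN marks
    a missing measurement.  ``covariates`` columns follow catalog order.
    ``imputed`` records patient ids whose target-week outcome was filled
    by LOCF.
    """

    patient_id: tuple[str, ...]
    arm: np.ndarray
    ppfvc: pd.DataFrame
    covariates: pd.DataFrame
    catalog: tuple[CovariateSpec, ...]
    delta_ppfvc: np.ndarray | None = None
    imputed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.patient_id)

    @property
    def weeks(self) -> list[int]:
        return list(self.ppfvc.columns)

    def validate(self) -> None:
        n = len(self.patient_id)
        if len(set(self.patient_id)) != n:
            dupes = sorted({p for p in self.patient_id if self.patient_id.count(p) > 1})
            raise ValidationError(f"duplicate patient_id: {dupes}")
        if self.arm.shape != (n,):
            raise ValidationError("arm length does not match patient count")
        bad = set(np.unique(self.arm)) - {0, 1}
        if bad:
            raise ValidationError(f"arm values outside {{0,1}}: {sorted(bad)}")
        if (self.arm == 1).sum() == 0 or (self.arm == 0).sum() == 0:
            raise ValidationError("both arms must be non-empty")
        if len(self.ppfvc) != n or len(self.covariates) != n:
            raise ValidationError("table lengths do not match patient count")
        if 0 not in self.ppfvc.columns:
            raise ValidationError("week-0 ppFVC column is required")
        w0 = self.ppfvc[0].to_numpy(float)
        if np.isnan(w0).any():
            missing = [self.patient_id[i] for i in np.nonzero(np.isnan(w0))[0]]
            raise ValidationError(f"missing week-0 ppFVC for patients: {missing}")
        cat_names = [s.name for s in self.catalog]
        if list(self.covariates.columns) != cat_names:
            raise ValidationError("covariate columns do not match catalog order")
        for spec in self.catalog:
            vals = self.covariates[spec.name].to_numpy(float)
            ok = np.isnan(vals)  # missing is flagged, not rejected, at load
            for v in vals[~ok]:
                if not spec.admissible(v):
                    raise ValidationError(
                        f"covariate {spec.name!r}: value {v!r} not admissible for kind {spec.kind}"
                    )
        if self.delta_ppfvc is not None and self.delta_ppfvc.shape != (n,):
            raise ValidationError("delta_ppfvc length does not match patient count")

    def missing_covariate_mask(self) -> pd.DataFrame:
        """Boolean mask of missing covariate cells (flagged, never zero-filled)."""
        return self.covariates.isna()

    def covariate_record(self, i: int) -> dict[str, float]:
        return {s.name: float(self.covariates[s.name].iloc[i]) for s in self.catalog}


def _parse_float(token: str, where: str) -> float:
    token = token.strip()
    if token == "NA" or token == "":
        return math.nan
    try:
        return float(token)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number {token!r} in {where}") from exc


def load_trial_table(path: str, catalog: Sequence[CovariateSpec]) -> TrialDataset:
    """Read a trial CSV (header row, "NA" missing) into a validated dataset.

    Expected columns: ``patient_id``, ``arm``, ``ppfvc_w<k>`` per visit
    week k, then one column per catalog covariate.  Unknown columns,
    arm values outside {0,1}, duplicate patient ids and a missing week-0
    ppFVC are all reported as :class:`ValidationError`.
    """
    catalog = list(catalog)
    cat_names = {s.name for s in catalog}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file")
        rows = list(reader)

    weeks: list[int] = []
    for col in header:
        if col in ("patient_id", "arm"):
            continue
        m = _PPFVC_COL.match(col)
        if m:
            weeks.append(int(m.group(1)))
        elif col not in cat_names:
            raise ValidationError(f"unknown column {col!r}")
    for required in ("patient_id", "arm"):
        if required not in header:
            raise ValidationError(f"missing required column {required!r}")
    for spec in catalog:
        if spec.name not in header:
            raise ValidationError(f"missing covariate column {spec.name!r}")

    idx = {col: k for k, col in enumerate(header)}
    pids: list[str] = []
    arms: list[int] = []
    pp = {w: [] for w in sorted(weeks)}
    cov = {s.name: [] for s in catalog}
    for rownum, row in enumerate(rows, start=2):
        if len(row) != len(header):
            raise ValidationError(f"row {rownum}: expected {len(header)} fields, got {len(row)}")
        pids.append(row[idx["patient_id"]])
        arm_tok = row[idx["arm"]].strip()
        if arm_tok not in ("0", "1"):
            raise ValidationError(f"row {rownum}: arm must be 0 or 1, got {arm_tok!r}")
        arms.append(int(arm_tok))
        for w in pp:
            pp[w].append(_parse_float(row[idx[f"ppfvc_w{w}"]], f"row {rownum}, ppfvc_w{w}"))
        for name in cov:
            cov[name].append(_parse_float(row[idx[name]], f"row {rownum}, {name}"))

    return TrialDataset(
        patient_id=tuple(pids),
        arm=np.asarray(arms, dtype=int),
        ppfvc=pd.DataFrame(pp),
        covariates=pd.DataFrame({s.name: cov[s.name] for s in catalog}),
        catalog=tuple(catalog),
    )


def _fmt(v: float) -> str:
    if math.isnan(v):
        return "NA"
    return repr(float(v))  # shortest round-trip representation


def write_trial_table(ds: TrialDataset, path: str) -> None:
    """Write the dataset in the load dialect (value-identical round trip)."""
    weeks = sorted(ds.ppfvc.columns)
    header = ["patient_id", "arm"] + [f"ppfvc_w{w}" for w in weeks] + [s.name for s in ds.catalog]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(ds.n):
            row = [ds.patient_id[i], str(int(ds.arm[i]))]
            row += [_fmt(float(ds.ppfvc[w].iloc[i])) for w in weeks]
            row += [_fmt(float(ds.covariates[s.name].iloc[i])) for s in ds.catalog]
            writer.writerow(row)


def locf_impute_outcome(ds: TrialDataset, target_week: int) -> TrialDataset:
    """Fill a missing target-week ppFVC with the latest earlier observation.

    Patients already complete are untouched.  The returned dataset's
    ``imputed`` field lists the patient ids that were carried forward.
    A patient with no earlier non-missing visit is an error.
    """
    if target_week not in ds.ppfvc.columns:
        raise ValidationError(f"unknown visit week {target_week}")
    col = ds.ppfvc[target_week].to_numpy(float).copy()
    earlier = sorted(w for w in ds.ppfvc.columns if w < target_week)
    imputed: list[str] = []
    hopeless: list[str] = []
    for i in np.nonzero(np.isnan(col))[0]:
        carried = math.nan
        for w in reversed(earlier):
            v = float(ds.ppfvc[w].iloc[i])
            if not math.isnan(v):
                carried = v
                break
        if math.isnan(carried):
            hopeless.append(ds.patient_id[i])
        else:
            col[i] = carried
            imputed.append(ds.patient_id[i])
    if hopeless:
        raise ValidationError(
            f"LOCF impossible (no earlier non-missing visit) for patients: {hopeless}"
        )
    pp = ds.ppfvc.copy()
    pp[target_week] = col
    return replace(ds, ppfvc=pp, imputed=tuple(imputed))


def compute_delta_ppfvc(ds: TrialDataset, target_week: int) -> TrialDataset:
    """Derive delta ppFVC = ppfvc[target_week] - ppfvc[0] (percentage points)."""
    if target_week not in ds.ppfvc.columns:
        raise ValidationError(f"unknown visit week {target_week}")
    tw = ds.ppfvc[target_week].to_numpy(float)
    if np.isnan(tw).any():
        missing = [ds.patient_id[i] for i in np.nonzero(np.isnan(tw))[0]]
        raise ValidationError(
            f"missing week-{target_week} ppFVC (run LOCF first) for patients: {missing}"
        )
    delta = tw - ds.ppfvc[0].to_numpy(float)
    return replace(ds, delta_ppfvc=delta)
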