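"""Error/deviation transformation and outlier handling for adjustment data.

Responses and element orientations are circular; before any linear modelling
they are re-expressed relative to the trial's ensemble mean: the response
becomes a signed "error" and each element orientation a signed "deviation",
both acute angle differences in [-90, 90).  Outlier trials are then removed
in a fixed order — gross errors, a per-subject interquartile-range fence on
the remaining errors, then slow responses — and subjects whose error SD
exceeds a threshold are excluded outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import acute_angle_diff, circular_mean_orientation
from .grid import DEV_COLUMNS, ORI_COLUMNS

__all__ = ["OutlierRules", "RemovalLog", "preprocess"]


@dataclass(frozen=True)
class OutlierRules:
    """Trial-removal and subject-exclusion thresholds.

    Defaults: errors larger than 45 deg in magnitude are removed first; the
    remaining errors are fenced per subject at quartile +/- 1.5 IQR;
    responses slower than 10 s are removed; finally subjects whose error SD
    exceeds 30 deg are excluded.
    """

    max_abs_error: float = 45.0
    iqr_multiplier: float = 1.5
    max_rt: float = 10.0
    subject_exclusion_sd: float = 30.0

    def __post_init__(self):
        for name in ("max_abs_error", "iqr_multiplier", "max_rt", "subject_exclusion_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RemovalLog:
    n_input: int = 0
    n_removed_by_rule: dict = field(default_factory=dict)
    fraction_removed: float = 0.0
    excluded_subjects: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_removed_by_rule": self.n_removed_by_rule,
                "fraction_removed": self.fraction_removed,
                "excluded_subjects": self.excluded_subjects,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _ensemble_means(df: pd.DataFrame, reference: str) -> np.ndarray:
    if reference == "generating_mean":
        return df["generating_mean_deg"].to_numpy(dtype=float)
    if reference == "sample_mean":
        oris = df[ORI_COLUMNS].to_numpy(dtype=float)
        return circular_mean_orientation(oris, axis=1)
    raise ValueError(f"reference must be 'sample_mean' or 'generating_mean', got {reference!r}")


def preprocess(trials: pd.DataFrame, rules: OutlierRules | None = None,
               reference: str = "sample_mean") -> tuple[pd.DataFrame, RemovalLog]:
    """Transform a trial table into errors/deviations and flag outliers.

    ``reference`` selects the "actual average orientation" of the ensemble:
    the sample circular mean of the 25 presented orientations (default; a
    uniform averager then has zero expected weights) or the generating mean
    of the stimulus distribution.

    Returns the table with added columns ``mean_deg``, ``error_deg``,
    ``dev_01..dev_25``, ``kept`` and ``removal_reason``, plus a
    :class:`RemovalLog`.  Excluded subjects keep their rows but all are
    marked not kept with reason ``subject_excluded``.
    """
    rules = rules or OutlierRules()
    required = {"subject_id", "report_deg", "rt_s", *ORI_COLUMNS}
    missing = sorted(required - set(trials.columns))
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")

    df = trials.copy()
    mean = _ensemble_means(df, reference)
    df["mean_deg"] = mean
    df["error_deg"] = acute_angle_diff(df["report_deg"].to_numpy(dtype=float), mean)
    devs = acute_angle_diff(df[ORI_COLUMNS].to_numpy(dtype=float), mean[:, None])
    df[DEV_COLUMNS] = devs
    df["kept"] = True
    df["removal_reason"] = ""

    log = RemovalLog(n_input=len(df))

    # rule 1: gross errors
    gross = df["error_deg"].abs() > rules.max_abs_error
    df.loc[gross, ["kept", "removal_reason"]] = [False, "max_abs_error"]
    log.n_removed_by_rule["max_abs_error"] = int(gross.sum())

    # rule 2: per-subject IQR fence on the remaining errors (two-sided)
    n_iqr = 0
    for _, idx in df[df["kept"]].groupby("subject_id").groups.items():
        errs = df.loc[idx, "error_deg"]
        q1, q3 = errs.quantile(0.25), errs.quantile(0.75)
        fence = rules.iqr_multiplier * (q3 - q1)
        out = (errs > q3 + fence) | (errs < q1 - fence)
        n_iqr += int(out.sum())
        df.loc[errs.index[out], ["kept", "removal_reason"]] = [False, "iqr"]
    log.n_removed_by_rule["iqr"] = n_iqr

    # rule 3: slow responses
    slow = df["kept"] & (df["rt_s"] > rules.max_rt)
    df.loc[slow, ["kept", "removal_reason"]] = [False, "max_rt"]
    log.n_removed_by_rule["max_rt"] = int(slow.sum())

    n_removed = int((~df["kept"]).sum())
    log.fraction_removed = n_removed / len(df) if len(df) else 0.0

    # Subject exclusion on the SD of the raw error distribution (before
    # trial removal): the 45-deg cut bounds kept errors, so a guessing
    # subject could never exceed the threshold on kept trials alone.
    for subject, grp in df.groupby("subject_id"):
        if grp["kept"].sum() == 0:
            log.excluded_subjects.append(str(subject))
            continue
        if grp["error_deg"].std(ddof=1) > rules.subject_exclusion_sd:
            log.excluded_subjects.append(str(subject))
    for subject in log.excluded_subjects:
        rows = df["subject_id"] == subject
        df.loc[rows & df["kept"], "removal_reason"] = "subject_excluded"
        df.loc[rows, "kept"] = False

    return df, log


def kept(df: pd.DataFrame) -> pd.DataFrame:
    """Convenience: the kept-trial subset of a preprocessed table."""
    return df[df["kept"]]
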