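"""Uncertainty analyses built on the oblique effect.

Orientation estimates are less precise near the obliques (45/135 deg) than
near the cardinals — the oblique effect.  Because the uncertainty of the
ensemble therefore varies with its average orientation, the central bias can
be charted against orientation: SWMs are re-fitted in sliding windows of the
folded (0-90 deg, cardinals collapsed) ensemble-mean axis, and the central
bias and error SD extracted per window.  A reliability-weighting observer
predicts a bias that grows from cardinals to obliques, mirroring the error
SD; a fixed-weight observer predicts a flat curve.

A complementary analysis conditions on the central element itself: in trials
whose ensemble mean is near an oblique, the central bias is compared across
close/mid/far bins of the central element's own distance to the oblique.
Under reliability weighting, an oblique central element is itself uncertain,
so the bias should grow close -> far.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circular import distance_to_oblique, fold_orientation
from .grid import CENTER_LOCATION, N_LOCATIONS, ORI_COLUMNS
from .group import bias_score, cohens_d, rm_anova
from .model import SpatialWeightModel

__all__ = [
    "BiasCurve",
    "SlopeTest",
    "DistanceBinResult",
    "sliding_window_bias",
    "bias_slope_test",
    "central_distance_binning",
]

BIN_LABELS = ("close", "mid", "far")


@dataclass
class BiasCurve:
    """Central bias and error SD as a function of folded ensemble orientation."""

    window_centers: np.ndarray          # degrees on the folded 0-90 axis
    per_subject_bias: np.ndarray        # (n_subjects, n_windows), NaN = too few trials
    per_subject_error_sd: np.ndarray    # same shape
    subjects: list
    window_width: float
    step: float
    target: int

    @property
    def central_bias(self) -> np.ndarray:
        """Group-mean bias per window (ignoring missing subjects)."""
        return np.nanmean(self.per_subject_bias, axis=0)

    @property
    def error_sd(self) -> np.ndarray:
        return np.nanmean(self.per_subject_error_sd, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, subject in enumerate(self.subjects):
            for j, c in enumerate(self.window_centers):
                rows.append({
                    "subject_id": subject, "window_center_deg": c,
                    "bias": self.per_subject_bias[i, j],
                    "error_sd_deg": self.per_subject_error_sd[i, j],
                })
        return pd.DataFrame(rows)


def _window_mask(folded: np.ndarray, center: float, half: float) -> np.ndarray:
    """Window membership on the folded axis, wrapping at 0/90 by reflection."""
    return (
        (np.abs(folded - center) <= half)
        | (np.abs(-folded - center) <= half)            # reflection at 0
        | (np.abs((180.0 - folded) - center) <= half)   # reflection at 90
    )


def sliding_window_bias(df: pd.DataFrame, window_width: float = 20.0,
                        step: float = 5.0, min_trials: int = 30,
                        target: int = CENTER_LOCATION) -> BiasCurve:
    """Per-subject central bias in sliding windows of the folded mean.

    Windows are centred on 0, step, 2*step, ... 90 with half-width
    ``window_width / 2``; a trial belongs to a window if its folded ensemble
    mean lies within the half-width (reflected at the 0 and 90 ends, since
    both are cardinals).  In every window with at least ``min_trials`` kept
    trials an SWM is fitted, the bias toward ``target`` (t-score at target
    minus mean t-score elsewhere) and the SD of errors recorded; windows
    with fewer trials are flagged missing (NaN), never zero.
    """
    if "kept" in df.columns:
        df = df[df["kept"]]
    half = window_width / 2.0
    centers = np.arange(0.0, 90.0 + 1e-9, step)
    subjects = sorted(df["subject_id"].unique())
    bias = np.full((len(subjects), centers.size), np.nan)
    err_sd = np.full_like(bias, np.nan)
    for i, subject in enumerate(subjects):
        grp = df[df["subject_id"] == subject]
        folded = fold_orientation(grp["mean_deg"].to_numpy(dtype=float))
        for j, c in enumerate(centers):
            sub = grp[_window_mask(folded, c, half)]
            if len(sub) < max(min_trials, 2):
                continue
            res = SpatialWeightModel.from_dataframe(sub, subject_id=subject).fit()
            bias[i, j] = bias_score(res, target=target)
            err_sd[i, j] = sub["error_deg"].std(ddof=1)
    return BiasCurve(window_centers=centers, per_subject_bias=bias,
                     per_subject_error_sd=err_sd, subjects=subjects,
                     window_width=window_width, step=step, target=target)


@dataclass(frozen=True)
class SlopeTest:
    """One-sample t-test of per-subject cardinal-to-oblique bias slopes."""

    mean_slope: float
    t: float
    p: float
    d_prime: float
    per_subject_slopes: np.ndarray


def bias_slope_test(curve: BiasCurve) -> SlopeTest:
    """Slope of the bias along the cardinal-to-oblique axis, tested across
    subjects.

    The abscissa is the distance of the window centre from the nearest
    cardinal (``min(c, 90 - c)``, running 0 -> 45), so a positive slope
    means more bias near the obliques.  Per subject an OLS slope over the
    non-missing windows; then a two-sided one-sample t-test against zero.
    """
    x_all = np.minimum(curve.window_centers, 90.0 - curve.window_centers)
    slopes = []
    for row in curve.per_subject_bias:
        ok = np.isfinite(row)
        if ok.sum() < 2:
            slopes.append(np.nan)
            continue
        x = x_all[ok] - x_all[ok].mean()
        slopes.append(float(x @ (row[ok] - row[ok].mean()) / (x @ x)))
    slopes = np.asarray(slopes)
    slopes = slopes[np.isfinite(slopes)]
    if slopes.size < 3:
        raise ValueError("at least 3 subjects with estimable slopes are required")
    t, p = stats.ttest_1samp(slopes, 0.0)
    try:
        d = cohens_d(slopes).d_prime
    except ValueError:  # identical slopes across subjects
        d = np.nan
    return SlopeTest(mean_slope=float(slopes.mean()), t=float(t), p=float(p),
                     d_prime=d, per_subject_slopes=slopes)


@dataclass
class DistanceBinResult:
    """Central bias by distance of the target element to the oblique."""

    bins: tuple
    bias_per_bin: np.ndarray   # (n_subjects, 3)
    subjects: list
    anova: "dict"
    location: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, subject in enumerate(self.subjects):
            for j, label in enumerate(self.bins):
                rows.append({"subject_id": subject, "bin": label,
                             "bias": self.bias_per_bin[i, j]})
        return pd.DataFrame(rows)


def central_distance_binning(df: pd.DataFrame, near_oblique_halfwidth: float = 10.0,
                             location: int = CENTER_LOCATION,
                             min_trials_per_bin: int = 26) -> DistanceBinResult:
    """Bias toward a location vs. that element's distance to the oblique.

    Keeps trials whose folded ensemble mean lies within ``45 +/-
    near_oblique_halfwidth``; splits each subject's trials into close/mid/far
    per-subject tertiles of the element's absolute distance to the nearest
    oblique; fits an SWM per bin and records the bias toward ``location``.
    The subject x bin table is then submitted to a one-way repeated-measures
    ANOVA.  Running the same analysis keyed to a non-central location is the
    natural control.
    """
    if "kept" in df.columns:
        df = df[df["kept"]]
    folded = fold_orientation(df["mean_deg"].to_numpy(dtype=float))
    near = df[np.abs(folded - 45.0) <= near_oblique_halfwidth]
    subjects = sorted(near["subject_id"].unique())
    ori_col = ORI_COLUMNS[location - 1]
    bias = np.full((len(subjects), 3), np.nan)
    for i, subject in enumerate(subjects):
        grp = near[near["subject_id"] == subject]
        d = distance_to_oblique(grp[ori_col].to_numpy(dtype=float))
        q1, q2 = np.quantile(d, [1 / 3, 2 / 3])
        masks = [d <= q1, (d > q1) & (d <= q2), d > q2]
        for j, mask in enumerate(masks):
            sub = grp[mask]
            if len(sub) < max(min_trials_per_bin, 2):
                raise ValueError(
                    f"bin {BIN_LABELS[j]!r} for subject {subject!r} has only "
                    f"{len(sub)} trials; widen near_oblique_halfwidth or relax "
                    f"min_trials_per_bin")
            res = SpatialWeightModel.from_dataframe(sub, subject_id=subject).fit()
            bias[i, j] = bias_score(res, target=location)
    table = pd.DataFrame({
        "subject_id": np.repeat(subjects, 3),
        "bin": np.tile(BIN_LABELS, len(subjects)),
        "bias": bias.ravel(),
    })
    anova = rm_anova(table, dv="bias", within="bin")
    return DistanceBinResult(bins=BIN_LABELS, bias_per_bin=bias, subjects=subjects,
                             anova=anova, location=location)
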