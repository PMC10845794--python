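"""The spatial weighted-average model (SWM).

The SWM is a per-observer linear regression of the trial response error on
the deviation of each of the 25 elements from the ensemble mean,

    error_j = sum_k  w_k * deviation_jk ,

with no intercept (errors and deviations are approximately zero-centred by
construction).  The coefficients w_k are the integration weights: a uniform
averager has equal weights everywhere, an observer who over-weights the
fovea has an inflated w at the central location.  The system is solved with
the Moore-Penrose pseudo-inverse, which returns the minimum-norm solution —
important because deviations computed against the sample mean sum to
(approximately) zero, so weights are identified only up to an additive
constant and the pseudo-inverse picks the zero-sum representative.

Weights are standardised into regression t-scores (weight / standard error)
before any group-level analysis, so observers with different noise levels
and trial counts are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .circular import acute_angle_diff
from .grid import DEV_COLUMNS, GRID_COLS, GRID_ROWS, N_LOCATIONS, ORI_COLUMNS, values_to_grid

__all__ = [
    "SpatialWeightModel",
    "SpatialWeightResults",
    "fit_swm",
    "fit_subject_maps",
    "response_stimulus_distance",
    "interpolate_map",
]


class SpatialWeightModel:
    """Linear model ``error ~ deviations`` for one observer (and condition).

    Parameters
    ----------
    endog : array-like, shape (J,)
        Trial response errors in signed degrees.
    exog : array-like, shape (J, 25)
        Per-trial element deviations, columns ordered by location index 1-25.
    subject_id, condition : optional labels carried through to the results.

    Examples
    --------
    >>> res = SpatialWeightModel(errors, deviations).fit()
    >>> res.tvalues[12]   # t-score at the central location (0-based 12)
    """

    #: row sums this small, relative to the design scale, mark a
    #: sample-mean-centred design (see `fit`)
    _CENTERED_REL_TOL = 0.2

    def __init__(self, endog, exog, subject_id: Optional[str] = None,
                 condition=None, zero_sum: Optional[bool] = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_LOCATIONS:
            raise ValueError(f"exog must be (J, {N_LOCATIONS}), got {X.shape}")
        if len(y) != X.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if len(y) < 2:
            raise ValueError("at least 2 trials are required to fit the SWM")
        if not np.any(X):
            raise ValueError("all-zero design matrix")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
            raise ValueError("non-finite values in the design")
        self.endog = y
        self.exog = X
        self.subject_id = subject_id
        self.condition = condition
        if zero_sum is None:
            # Deviations computed against the sample circular mean sum to
            # (numerically almost) zero within each trial, leaving the weights
            # identified only up to an additive constant; detect that case
            # from the relative size of the row sums.
            row = X @ np.ones(N_LOCATIONS)
            scale = np.sqrt(np.mean(X ** 2)) * np.sqrt(N_LOCATIONS)
            rel = np.sqrt(np.mean(row ** 2)) / scale if scale > 0 else 0.0
            zero_sum = bool(rel < self._CENTERED_REL_TOL)
        self.zero_sum = zero_sum

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_id: Optional[str] = None,
                       condition=None) -> "SpatialWeightModel":
        """Build the model from a preprocessed trial table.

        Uses the ``error_deg`` and ``dev_01..dev_25`` columns; rows flagged
        not kept are dropped.
        """
        if "kept" in df.columns:
            df = df[df["kept"]]
        missing = [c for c in ["error_deg", *DEV_COLUMNS] if c not in df.columns]
        if missing:
            raise ValueError(f"preprocessed table missing columns: {missing}")
        return cls(df["error_deg"].to_numpy(), df[DEV_COLUMNS].to_numpy(),
                   subject_id=subject_id, condition=condition)

    def fit(self) -> "SpatialWeightResults":
        """Estimate weights by minimum-norm least squares (pseudo-inverse).

        Standard errors come from the pseudo-inverse covariance
        ``sigma2 * pinv(X'X)`` with residual variance ``RSS / (J - rank(X))``
        — rank, not 25, so t-scores stay defined under the rank deficiency
        induced by sample-mean centring of the deviations.

        When the design is detected (or declared) as sample-mean centred,
        the fit is carried out in the zero-row-sum subspace — each row of X
        is centred before solving — so the returned weights are exactly the
        zero-sum representative.  Rows then sum to zero only approximately
        (circular means are not arithmetic means), and leaving the raw
        near-null direction in the solve would let it absorb noise with a
        huge variance amplification, shifting all 25 weights by an arbitrary
        constant per fit.
        """
        X, y = self.exog, self.endog
        if self.zero_sum:
            X = X - X.mean(axis=1, keepdims=True)
        weights = np.linalg.pinv(X) @ y
        resid = y - X @ weights
        rank = int(np.linalg.matrix_rank(X))
        df_resid = len(y) - rank
        rss = float(resid @ resid)
        sigma2 = rss / df_resid if df_resid > 0 else np.nan
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        tvalues = np.divide(weights, bse, out=np.zeros_like(weights), where=bse > 0)
        return SpatialWeightResults(
            model=self, params=weights, bse=bse, tvalues=tvalues,
            resid=resid, rank=rank, df_resid=df_resid, sigma2=sigma2,
            n_trials=len(y), rank_deficient=rank < N_LOCATIONS,
            subject_id=self.subject_id, condition=self.condition,
        )


@dataclass
class SpatialWeightResults:
    """Fitted weight map for one observer: weights, SEs, t-scores."""

    model: SpatialWeightModel
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    resid: np.ndarray
    rank: int
    df_resid: int
    sigma2: float
    n_trials: int
    rank_deficient: bool
    subject_id: Optional[str] = None
    condition: object = None

    # the field-facing aliases
    @property
    def weights(self) -> np.ndarray:
        return self.params

    @property
    def standard_errors(self) -> np.ndarray:
        return self.bse

    @property
    def t_scores(self) -> np.ndarray:
        return self.tvalues

    def weight_grid(self) -> np.ndarray:
        return values_to_grid(self.params)

    def tvalue_grid(self) -> np.ndarray:
        return values_to_grid(self.tvalues)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "n_trials": self.n_trials,
            "rank": self.rank,
            "rank_deficient": self.rank_deficient,
            "weights": self.params.tolist(),
            "standard_errors": self.bse.tolist(),
            "t_scores": self.tvalues.tolist(),
        }

    def summary(self) -> str:
        """Plain-text summary table of the fitted weight map."""
        lines = [
            "Spatial weighted-average model",
            "==============================",
            f"subject: {self.subject_id or '-'}    condition: {self.condition if self.condition is not None else '-'}",
            f"trials: {self.n_trials}    rank: {self.rank}"
            f"{' (rank deficient)' if self.rank_deficient else ''}    df_resid: {self.df_resid}",
            f"residual SD: {np.sqrt(self.sigma2):.3f} deg",
            "",
            f"{'loc':>3} {'weight':>9} {'SE':>8} {'t':>8}",
        ]
        for k in range(N_LOCATIONS):
            lines.append(f"{k + 1:>3} {self.params[k]:>9.4f} {self.bse[k]:>8.4f} "
                         f"{self.tvalues[k]:>8.3f}")
        return "\n".join(lines)


def fit_swm(exog, endog, subject_id: Optional[str] = None,
            condition=None) -> SpatialWeightResults:
    """Convenience wrapper: fit the SWM from a design matrix and errors."""
    return SpatialWeightModel(endog, exog, subject_id=subject_id,
                              condition=condition).fit()


def fit_subject_maps(df: pd.DataFrame, condition_col: Optional[str] = None
                     ) -> dict:
    """Fit one SWM per subject (optionally per condition level).

    Returns ``{subject_id: results}`` or, with ``condition_col``,
    ``{(subject_id, level): results}``.  Rows flagged not kept are ignored;
    subjects with no kept rows are skipped.
    """
    if "kept" in df.columns:
        df = df[df["kept"]]
    out = {}
    if condition_col is None:
        for subject, grp in df.groupby("subject_id", sort=True):
            out[subject] = SpatialWeightModel.from_dataframe(grp, subject_id=subject).fit()
    else:
        for (subject, level), grp in df.groupby(["subject_id", condition_col], sort=True):
            out[(subject, level)] = SpatialWeightModel.from_dataframe(
                grp, subject_id=subject, condition=level).fit()
    return out


def response_stimulus_distance(df: pd.DataFrame) -> np.ndarray:
    """Mean absolute acute distance between the report and each element.

    A model-free mirror of the weight map: locations that pull the report
    show smaller distances.  Returns 25 values in [0, 90], location order.
    """
    if "kept" in df.columns:
        df = df[df["kept"]]
    if df.empty:
        raise ValueError("no kept trials")
    reports = df["report_deg"].to_numpy(dtype=float)[:, None]
    oris = df[ORI_COLUMNS].to_numpy(dtype=float)
    return np.abs(acute_angle_diff(reports, oris)).mean(axis=0)


def interpolate_map(values, upsample_factor: int = 10) -> np.ndarray:
    """Bilinear upsampling of a 25-location map for heat-map display.

    The 5x5 node values are reproduced exactly; ``upsample_factor`` 1 is the
    identity.
    """
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    grid = values_to_grid(values)
    if upsample_factor == 1:
        return grid
    from scipy.interpolate import RegularGridInterpolator

    rows = np.arange(GRID_ROWS, dtype=float)
    cols = np.arange(GRID_COLS, dtype=float)
    interp = RegularGridInterpolator((rows, cols), grid, method="linear")
    nr = (GRID_ROWS - 1) * upsample_factor + 1
    nc = (GRID_COLS - 1) * upsample_factor + 1
    rr = np.linspace(0, GRID_ROWS - 1, nr)
    cc = np.linspace(0, GRID_COLS - 1, nc)
    pts = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(pts)
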