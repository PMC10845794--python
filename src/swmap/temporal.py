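"""Serial-position analysis for sequentially presented ensembles.

When element onsets are randomised, a spatial bias can be followed through
time: for a given location, SWMs are re-fitted on the subsets of trials in
which that element occupied a moving window of serial positions, and the
weight of that element extracted from each fit.  Rows of the resulting
location x serial-position matrix are the timecourses of the biases.  Data
are pooled across participants after z-scoring each participant's errors, so
observers with different precision contribute equally.

The shape of a timecourse (steady rise vs. primacy/recency) is characterised
by comparing polynomial fits of order 1-4 under split-half cross-validation:
participants are repeatedly split in half, the timecourse re-estimated from
the training half, each polynomial fitted to it, and its predictions
correlated with the test-half timecourse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import DEV_COLUMNS, N_LOCATIONS, ONSET_COLUMNS, RANK_COLUMNS
from .model import SpatialWeightModel

__all__ = [
    "SerialWeightMatrix",
    "PolyCVResult",
    "rank_serial_positions",
    "add_serial_ranks",
    "aggregate_and_zscore",
    "serial_swm_matrix",
    "serial_timecourse",
    "polynomial_model_comparison",
    "serial_timecourse_cv",
    "cross_condition_prediction",
    "CrossConditionResult",
]


def rank_serial_positions(onsets) -> np.ndarray:
    """Serial ranks (1-based) of the 25 element onsets.

    Ties share the minimum rank of the tied group (competition ranking): two
    elements appearing first both get rank 1 and the next gets rank 3.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.ndim == 1:
        onsets = onsets[None, :]
        squeeze = True
    else:
        squeeze = False
    if onsets.shape[-1] != N_LOCATIONS or not np.all(np.isfinite(onsets)):
        raise ValueError("onsets must be 25 finite values per trial; "
                         "simultaneous designs have no serial positions")
    ranks = rankdata(onsets, method="min", axis=1).astype(int)
    return ranks[0] if squeeze else ranks


def add_serial_ranks(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``rank_01..rank_25`` columns computed from the onset columns."""
    onsets = df[ONSET_COLUMNS].to_numpy(dtype=float)
    if np.isnan(onsets).any():
        raise ValueError("missing onsets: serial ranks require a jittered design")
    out = df.copy()
    out[RANK_COLUMNS] = rank_serial_positions(onsets)
    return out


def aggregate_and_zscore(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Pool subjects after z-scoring each subject's error distribution.

    Adds an ``error_z`` column (per-subject mean 0, sample SD 1); deviations
    stay in degrees.  Subjects with fewer than 2 kept trials cannot be
    z-scored and are dropped; their ids are returned as the log.
    """
    if "kept" in df.columns:
        df = df[df["kept"]]
    subjects = df["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("pooling requires at least 2 subjects")
    dropped = []
    parts = []
    for subject, grp in df.groupby("subject_id", sort=True):
        if len(grp) < 2 or grp["error_deg"].std(ddof=1) == 0:
            dropped.append(str(subject))
            continue
        grp = grp.copy()
        grp["error_z"] = ((grp["error_deg"] - grp["error_deg"].mean())
                          / grp["error_deg"].std(ddof=1))
        parts.append(grp)
    return pd.concat(parts, ignore_index=True), dropped


@dataclass
class SerialWeightMatrix:
    """Location x serial-position-window matrix of weights or t-scores."""

    matrix: np.ndarray            # (25, n_windows); NaN = too few trials
    window_size: int
    window_positions: np.ndarray  # start ranks, 1-based
    n_trials_per_cell: np.ndarray
    value: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(range(1, N_LOCATIONS + 1), name="location"),
            columns=pd.Index(self.window_positions, name="window_start"),
        )


class _PooledDesign:
    """Precomputed arrays for fast repeated window fits on pooled data."""

    def __init__(self, pooled: pd.DataFrame):
        self.X = pooled[DEV_COLUMNS].to_numpy(dtype=float)
        self.y = pooled["error_z"].to_numpy(dtype=float)
        self.ranks = pooled[RANK_COLUMNS].to_numpy(dtype=int)
        self.subjects = pooled["subject_id"].to_numpy()

    def subject_mask(self, subject_ids) -> np.ndarray:
        return np.isin(self.subjects, np.asarray(subject_ids))

    def cell_value(self, location: int, start: int, window_size: int,
                   min_trials: int, value: str,
                   row_mask: np.ndarray | None = None):
        loc_ranks = self.ranks[:, location - 1]
        mask = (loc_ranks >= start) & (loc_ranks <= start + window_size - 1)
        if row_mask is not None:
            mask &= row_mask
        n = int(mask.sum())
        if n < max(min_trials, 2):
            return np.nan, n
        res = SpatialWeightModel(self.y[mask], self.X[mask]).fit()
        v = res.tvalues if value == "tscore" else res.params
        return float(v[location - 1]), n


def serial_swm_matrix(pooled: pd.DataFrame, window_size: int = 3,
                      n_windows: int | None = None, min_trials: int = 30,
                      value: str = "tscore",
                      locations: Sequence[int] | None = None) -> SerialWeightMatrix:
    """Weight of each element as a function of its own serial position.

    For location L and window start w, an SWM is fitted to the pooled trials
    in which L's rank falls in [w, w + window_size - 1] (the other elements'
    ranks are free to vary), and the weight (default: t-score) of L is taken
    from that fit.  With 25 ranks and a window of 3 there are up to 23
    window positions; ``n_windows`` can restrict this.  Cells with fewer
    than ``min_trials`` trials are flagged missing (NaN).
    """
    if not {"error_z", *RANK_COLUMNS}.issubset(pooled.columns):
        raise ValueError("pooled table must carry error_z and rank_01..rank_25 "
                         "(see aggregate_and_zscore / add_serial_ranks)")
    max_windows = N_LOCATIONS - window_size + 1
    n_windows = max_windows if n_windows is None else min(n_windows, max_windows)
    starts = np.arange(1, n_windows + 1)
    locs = list(locations) if locations is not None else list(range(1, N_LOCATIONS + 1))
    design = _PooledDesign(pooled)
    matrix = np.full((N_LOCATIONS, n_windows), np.nan)
    counts = np.zeros((N_LOCATIONS, n_windows), dtype=int)
    for L in locs:
        for j, w in enumerate(starts):
            matrix[L - 1, j], counts[L - 1, j] = design.cell_value(
                L, w, window_size, min_trials, value)
    return SerialWeightMatrix(matrix=matrix, window_size=window_size,
                              window_positions=starts, n_trials_per_cell=counts,
                              value=value)


def serial_timecourse(pooled: pd.DataFrame, location: int, window_size: int = 3,
                      n_windows: int | None = None, min_trials: int = 30,
                      value: str = "tscore") -> np.ndarray:
    """One row of the serial weight matrix, for a single location."""
    mat = serial_swm_matrix(pooled, window_size=window_size, n_windows=n_windows,
                            min_trials=min_trials, value=value, locations=[location])
    return mat.matrix[location - 1]


@dataclass
class PolyCVResult:
    """Split-half cross-validated polynomial model comparison."""

    orders: tuple
    mean_correlation: dict        # order -> mean train-test correlation
    best_order: int
    coefficients: np.ndarray      # highest order first (np.polyfit layout)
    n_splits: int
    n_skipped: int

    def to_dict(self) -> dict:
        return {
            "orders": list(self.orders),
            "mean_correlation": {str(k): v for k, v in self.mean_correlation.items()},
            "best_order": self.best_order,
            "coefficients": self.coefficients.tolist(),
            "n_splits": self.n_splits,
            "n_skipped": self.n_skipped,
        }


def _fit_predict_poly(x: np.ndarray, tc: np.ndarray, order: int) -> np.ndarray:
    ok = np.isfinite(tc)
    coeffs = np.polyfit(x[ok], tc[ok], order)
    return np.polyval(coeffs, x)


def polynomial_model_comparison(timecourses, orders: Sequence[int] = (1, 2, 3, 4),
                                n_splits: int = 10_000,
                                rng: np.random.Generator | None = None,
                                subject_ids: Sequence | None = None) -> PolyCVResult:
    """Which polynomial order best describes a weight timecourse?

    ``timecourses`` is either an (n_subjects, W) array of per-subject series
    or a callable mapping a subject-id subset to a pooled series of length W
    (used to re-estimate the timecourse from each training half).  For each
    of ``n_splits`` random half-splits of the subjects, every polynomial
    order is fitted to the training-half timecourse (on centred window
    indices, reducing collinearity between orders) and its predictions are
    correlated with the test-half timecourse.  Splits whose test timecourse
    is constant are skipped and counted.

    Requires at least 4 subjects and more window positions than the largest
    order.
    """
    rng = rng or np.random.default_rng()
    orders = tuple(orders)
    if callable(timecourses):
        if subject_ids is None:
            raise ValueError("subject_ids are required with a callable timecourse")
        subject_ids = np.asarray(list(subject_ids))
        n_subj = len(subject_ids)
        full = np.asarray(timecourses(subject_ids), dtype=float)

        def half_tc(idx):
            return np.asarray(timecourses(subject_ids[idx]), dtype=float)
    else:
        mat = np.asarray(timecourses, dtype=float)
        if mat.ndim != 2:
            raise ValueError("per-subject timecourses must be a 2-D array")
        n_subj = mat.shape[0]
        full = np.nanmean(mat, axis=0)

        def half_tc(idx):
            return np.nanmean(mat[idx], axis=0)

    if n_subj < 4:
        raise ValueError("at least 4 subjects are required for split-half CV")
    W = full.size
    if W < max(orders) + 1:
        raise ValueError("more window positions than polynomial coefficients required")
    x = np.arange(W, dtype=float)
    x -= x.mean()

    sums = {m: 0.0 for m in orders}
    used = 0
    skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n_subj)
        train_idx, test_idx = perm[: n_subj // 2], perm[n_subj // 2:]
        train_tc = half_tc(train_idx)
        test_tc = half_tc(test_idx)
        ok = np.isfinite(train_tc) & np.isfinite(test_tc)
        if ok.sum() < max(orders) + 2 or np.nanstd(test_tc[ok]) == 0:
            skipped += 1
            continue
        for m in orders:
            pred = _fit_predict_poly(x, np.where(ok, train_tc, np.nan), m)
            if np.std(pred[ok]) == 0:
                r = 0.0  # constant prediction carries no information
            else:
                r = np.corrcoef(pred[ok], test_tc[ok])[0, 1]
            sums[m] += r
        used += 1
    if used == 0:
        raise ValueError("all splits degenerate: cannot compare models")
    mean_corr = {m: sums[m] / used for m in orders}
    best = max(orders, key=lambda m: mean_corr[m])
    ok = np.isfinite(full)
    coeffs = np.polyfit(x[ok], full[ok], best)
    return PolyCVResult(orders=orders, mean_correlation=mean_corr, best_order=best,
                        coefficients=coeffs, n_splits=n_splits, n_skipped=skipped)


def serial_timecourse_cv(pooled: pd.DataFrame, location: int, window_size: int = 3,
                         n_windows: int | None = None, min_trials: int = 20,
                         value: str = "tscore", orders: Sequence[int] = (1, 2, 3, 4),
                         n_splits: int = 10_000,
                         rng: np.random.Generator | None = None) -> PolyCVResult:
    """Split-half polynomial comparison with the timecourse re-estimated
    from the pooled z-scored data of each subject half."""
    design = _PooledDesign(pooled)
    max_windows = N_LOCATIONS - window_size + 1
    n_win = max_windows if n_windows is None else min(n_windows, max_windows)
    starts = np.arange(1, n_win + 1)
    subject_ids = np.unique(design.subjects)

    def tc_fn(ids):
        row_mask = design.subject_mask(ids)
        return np.array([
            design.cell_value(location, w, window_size, min_trials, value,
                              row_mask=row_mask)[0]
            for w in starts
        ])

    return polynomial_model_comparison(tc_fn, orders=orders, n_splits=n_splits,
                                       rng=rng, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# Cross-condition single-trial prediction
# ---------------------------------------------------------------------------

@dataclass
class CrossConditionResult:
    """Can weights from one condition predict single-trial errors in another?"""

    per_subject: pd.DataFrame     # columns: subject_id, test_level, correlation
    null_median: float
    null_q01: float
    null_q99: float
    train_level: object
    k: int

    def mean_correlation(self, test_level=None) -> float:
        df = self.per_subject
        if test_level is not None:
            df = df[df["test_level"] == test_level]
        return float(df["correlation"].mean())


def cross_condition_prediction(df: pd.DataFrame, condition_col: str,
                               train_level, test_levels=None, k: int = 5,
                               rng: np.random.Generator | None = None,
                               n_shuffles: int = 200) -> CrossConditionResult:
    """Predict single-trial errors in one condition from weights fitted in
    another, under k-fold cross-validation within subject.

    For each subject, the ``train_level`` trials are split into ``k`` folds;
    weights fitted on k-1 folds predict errors as ``X @ w`` — for the
    held-out fold when the test level equals the training level, and for all
    test-level trials otherwise.  The reported statistic is the Pearson
    correlation between predicted and observed errors, averaged over folds.
    A chance band comes from shuffling the observed errors across trials
    (``n_shuffles`` per subject and level): its median and 1st/99th
    percentiles are reported.  Subjects missing a condition are skipped.
    """
    rng = rng or np.random.default_rng()
    if "kept" in df.columns:
        df = df[df["kept"]]
    levels = sorted(df[condition_col].unique())
    if train_level not in levels:
        raise ValueError(f"train level {train_level!r} not present in {condition_col}")
    if test_levels is None:
        test_levels = levels
    rows = []
    null_rs = []
    for subject, grp in df.groupby("subject_id", sort=True):
        train = grp[grp[condition_col] == train_level]
        if len(train) < 2 * k:
            continue
        Xtr = train[DEV_COLUMNS].to_numpy(dtype=float)
        ytr = train["error_deg"].to_numpy(dtype=float)
        fold_ids = rng.permutation(len(train)) % k
        for level in test_levels:
            test = grp[grp[condition_col] == level]
            if test.empty:
                continue
            Xte = test[DEV_COLUMNS].to_numpy(dtype=float)
            yte = test["error_deg"].to_numpy(dtype=float)
            fold_rs = []
            pred_all = np.zeros(len(test))
            for f in range(k):
                w = np.linalg.pinv(Xtr[fold_ids != f]) @ ytr[fold_ids != f]
                if level == train_level:
                    hold = fold_ids == f
                    pred = Xtr[hold] @ w
                    obs = ytr[hold]
                else:
                    pred = Xte @ w
                    obs = yte
                    pred_all += pred / k
                if obs.size >= 3 and np.std(pred) > 0 and np.std(obs) > 0:
                    fold_rs.append(np.corrcoef(pred, obs)[0, 1])
            if not fold_rs:
                continue
            rows.append({"subject_id": subject, "test_level": level,
                         "correlation": float(np.mean(fold_rs))})
            # chance band: correlation after shuffling observed errors
            obs = yte if level != train_level else ytr
            pred = pred_all if level != train_level else Xtr @ (np.linalg.pinv(Xtr) @ ytr)
            for _ in range(n_shuffles):
                null_rs.append(np.corrcoef(pred, rng.permutation(obs))[0, 1])
    if not rows:
        raise ValueError("no subject had enough trials in the training condition")
    null_rs = np.asarray(null_rs)
    return CrossConditionResult(
        per_subject=pd.DataFrame(rows),
        null_median=float(np.median(null_rs)),
        null_q01=float(np.quantile(null_rs, 0.01)),
        null_q99=float(np.quantile(null_rs, 0.99)),
        train_level=train_level, k=k,
    )
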