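"""Group-level inference on spatial weight maps.

Significance against the uniform-pooling null is assessed with a location-
shuffling permutation test: each observer's 25 location scores are randomly
re-assigned to locations, breaking any weight-location correspondence while
preserving each observer's score distribution.  The group mean at each
location is compared with the surrogate distribution one-sidedly (surrogate
>= observed), with a Bonferroni-corrected alpha over the 25 locations.

Condition effects (ensemble SD, exposure duration) use the two-stage scheme:
per subject and location, an OLS slope of the weight on the condition level;
the slope maps then enter the same permutation machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import CENTER_LOCATION, N_LOCATIONS
from .model import SpatialWeightResults

__all__ = [
    "GroupWeightMap",
    "ConditionEffectMap",
    "AnovaResult",
    "EffectSize",
    "permutation_location_test",
    "bias_score",
    "condition_effect_map",
    "rm_anova",
    "cohens_d",
]


def _score_matrix(maps, value: str = "tscore") -> np.ndarray:
    """Coerce per-subject maps into an (n_subjects, 25) array.

    Accepts an array, a sequence of 25-vectors, or a sequence/mapping of
    :class:`SpatialWeightResults`.
    """
    if isinstance(maps, Mapping):
        maps = list(maps.values())
    rows = []
    for m in maps:
        if isinstance(m, SpatialWeightResults):
            rows.append(m.tvalues if value == "tscore" else m.params)
        else:
            rows.append(np.asarray(m, dtype=float))
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != N_LOCATIONS:
        raise ValueError(f"expected (n_subjects, {N_LOCATIONS}) scores, got {mat.shape}")
    return mat


@dataclass
class GroupWeightMap:
    """Group-mean location scores with permutation p-values."""

    mean_t: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_subjects: int
    alpha: float
    correction: str
    n_permutations: int

    @property
    def alpha_corrected(self) -> float:
        return self.alpha / N_LOCATIONS if self.correction == "bonferroni" else self.alpha

    def to_dict(self) -> dict:
        return {
            "mean_t": self.mean_t.tolist(),
            "p_values": self.p_values.tolist(),
            "significant": self.significant.tolist(),
            "n_subjects": self.n_subjects,
            "alpha": self.alpha,
            "correction": self.correction,
            "n_permutations": self.n_permutations,
        }


def _location_permutation_pvalues(scores: np.ndarray, n_permutations: int,
                                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One-sided permutation p-values for location means.

    Shuffles each subject's location<->score correspondence independently in
    every permutation, averages across subjects, and counts surrogates at
    least as large as the observed mean (add-one corrected).
    """
    observed = scores.mean(axis=0)
    n_subj = scores.shape[0]
    tiled = np.broadcast_to(scores, (n_permutations, n_subj, N_LOCATIONS)).copy()
    surrogate = rng.permuted(tiled, axis=2).mean(axis=1)
    exceed = (surrogate >= observed).sum(axis=0)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return observed, p


def permutation_location_test(maps, n_permutations: int = 10_000, alpha: float = 0.05,
                              correction: str = "bonferroni",
                              rng: np.random.Generator | None = None,
                              value: str = "tscore") -> GroupWeightMap:
    """Test which locations carry more weight than uniform pooling predicts.

    ``maps`` is anything :func:`_score_matrix` accepts (per-subject t-score
    vectors or fitted results).  Requires at least 2 subjects.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    scores = _score_matrix(maps, value=value)
    if scores.shape[0] < 2:
        raise ValueError("at least 2 subjects are required")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-value resolution is degraded",
                      stacklevel=2)
    rng = rng or np.random.default_rng()
    observed, p = _location_permutation_pvalues(scores, n_permutations, rng)
    alpha_corr = alpha / N_LOCATIONS if correction == "bonferroni" else alpha
    return GroupWeightMap(
        mean_t=observed, p_values=p, significant=p < alpha_corr,
        n_subjects=scores.shape[0], alpha=alpha, correction=correction,
        n_permutations=n_permutations,
    )


def bias_score(map_or_scores, target: int = CENTER_LOCATION,
               controls: Sequence[int] | None = None) -> float:
    """Bias toward one location: its score minus the mean control score.

    ``target`` and ``controls`` are 1-based location indices; controls
    default to all other 24 locations.  Positive values mean the target
    location pulls the report more than the controls do.  Invariant to
    adding a constant to all scores (the additive ambiguity of minimum-norm
    weights).
    """
    if isinstance(map_or_scores, SpatialWeightResults):
        scores = map_or_scores.tvalues
    else:
        scores = np.asarray(map_or_scores, dtype=float)
    if scores.shape != (N_LOCATIONS,):
        raise ValueError(f"expected {N_LOCATIONS} scores, got shape {scores.shape}")
    if controls is None:
        controls = [k for k in range(1, N_LOCATIONS + 1) if k != target]
    controls = list(controls)
    if not controls:
        raise ValueError("controls must be nonempty")
    if target in controls:
        raise ValueError("target must not appear among controls")
    for k in [target, *controls]:
        if not 1 <= k <= N_LOCATIONS:
            raise ValueError(f"location index {k} out of range 1..{N_LOCATIONS}")
    idx = np.asarray(controls) - 1
    return float(scores[target - 1] - scores[idx].mean())


@dataclass
class ConditionEffectMap:
    """Per-location slopes of weight on a condition level, with p-values."""

    slopes: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    levels: np.ndarray
    per_subject_slopes: np.ndarray
    n_permutations: int
    alpha: float
    correction: str

    def to_dict(self) -> dict:
        return {
            "slopes": self.slopes.tolist(),
            "p_values": self.p_values.tolist(),
            "significant": self.significant.tolist(),
            "levels": self.levels.tolist(),
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "correction": self.correction,
        }


def condition_effect_map(maps: Mapping, levels: Sequence[float],
                         n_permutations: int = 10_000, alpha: float = 0.05,
                         correction: str = "bonferroni",
                         rng: np.random.Generator | None = None,
                         value: str = "weight") -> ConditionEffectMap:
    """Second-stage linear model: how weights change with a condition level.

    ``maps`` maps ``(subject_id, level)`` to a fitted map (or 25-vector);
    every subject must have a map at every level.  Per subject and location
    an OLS slope of the score on the level is computed; the group map is the
    mean slope and p-values come from the location-shuffling permutation
    test applied to the per-subject slope maps (one-sided: increases).

    By default slopes are computed on raw weights; ``value="tscore"`` uses
    t-scores instead.
    """
    levels = np.asarray(sorted(levels), dtype=float)
    if levels.size < 2:
        raise ValueError("at least 2 condition levels are required")
    subjects = sorted({key[0] for key in maps.keys()})
    stack = np.empty((len(subjects), levels.size, N_LOCATIONS))
    for i, subject in enumerate(subjects):
        for j, level in enumerate(levels):
            key = (subject, level)
            if key not in maps:
                # levels may be ints in the mapping
                alt = (subject, int(level)) if float(level).is_integer() else None
                if alt is not None and alt in maps:
                    key = alt
                else:
                    raise ValueError(f"missing map for subject {subject!r} at level {level}")
            stack[i, j] = _score_matrix([maps[key]], value=value)[0]

    x = levels - levels.mean()
    denom = float(x @ x)
    slopes = np.einsum("j,ijk->ik", x, stack) / denom  # (n_subjects, 25)

    rng = rng or np.random.default_rng()
    observed, p = _location_permutation_pvalues(slopes, n_permutations, rng)
    alpha_corr = alpha / N_LOCATIONS if correction == "bonferroni" else alpha
    return ConditionEffectMap(
        slopes=observed, p_values=p, significant=p < alpha_corr, levels=levels,
        per_subject_slopes=slopes, n_permutations=n_permutations,
        alpha=alpha, correction=correction,
    )


@dataclass(frozen=True)
class AnovaResult:
    """One within-subject ANOVA effect: F, dfs, p and partial eta squared."""

    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str = "subject_id"
             ) -> dict[str, AnovaResult]:
    """Repeated-measures ANOVA with 1 or 2 within-subject factors.

    The table must be complete and balanced (every subject contributes one
    value per factor-level cell).  Returns one :class:`AnovaResult` per
    effect, keyed by the factor name(s); partial eta squared is computed as
    ``F*df1 / (F*df1 + df2)``.
    """
    import pingouin as pg

    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    counts = data.groupby([subject, *within_list], observed=True)[dv].count()
    n_cells = data[subject].nunique() * int(np.prod([data[f].nunique()
                                                     for f in within_list]))
    if counts.empty or len(counts) != n_cells or counts.min() != 1 or counts.max() != 1:
        raise ValueError("unbalanced table: need exactly one value per subject x cell")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.rm_anova(data=data, dv=dv,
                            within=within_list if len(within_list) > 1 else within_list[0],
                            subject=subject, detailed=True)
    out = {}
    for _, row in table.iterrows():
        if str(row["Source"]).lower() == "error":
            continue
        # constant data: pingouin omits F entirely (SS identically zero)
        F = float(row["F"]) if "F" in row and np.isfinite(row.get("F", np.nan)) else 0.0
        df1 = int(row["ddof1"]) if "ddof1" in row else int(row["DF"])
        df2 = int(row["ddof2"]) if "ddof2" in row else int(table.iloc[-1]["DF"])
        p = float(row["p_unc"]) if "p_unc" in row and np.isfinite(row.get("p_unc", np.nan)) else 1.0
        out[str(row["Source"])] = AnovaResult(
            F=F, df1=df1, df2=df2, p=p,
            partial_eta_sq=(F * df1) / (F * df1 + df2) if F * df1 + df2 > 0 else 0.0,
        )
    return out


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d of a set of values against a reference."""

    d_prime: float
    n: int


def cohens_d(values, reference=0.0) -> EffectSize:
    """Cohen's d: mean / SD of ``values - reference`` (sample SD, n-1).

    ``reference`` may be a scalar (test against a constant) or a paired
    vector (test of a paired difference).
    """
    values = np.asarray(values, dtype=float)
    diffs = values - np.asarray(reference, dtype=float)
    if diffs.size < 2:
        raise ValueError("at least 2 values are required")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: effect size undefined")
    return EffectSize(d_prime=float(diffs.mean() / sd), n=int(diffs.size))
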