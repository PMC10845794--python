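"""Synthetic ensemble-orientation experiments and candidate observer models.

This module generates trial tables that mimic the four experimental designs
used in spatial-weighted-average studies of orientation ensemble perception:
5x5 grids of Gabor patches whose orientations are drawn around a random trial
mean, shown either simultaneously (at one of several durations and ensemble
SDs) or with randomised element onsets.  Responses are produced by candidate
observer models:

``uniform``
    the circular mean of all 25 elements plus motor noise — the classic
    uniform-pooling account.
``fixed_weights``
    a weighted circular mean with a fixed (optionally rank-dependent)
    nonnegative weight profile — anisotropic pooling with a constant bias.
``reliability_weighted``
    a two-cue model: a foveal cue (the central element, corrupted by foveal
    encoding noise) and a parafoveal cue (the circular mean of the other 24,
    corrupted by noise that grows with the ensemble SD), combined by
    inverse-variance weighting on the orientation circle.  Only this model
    predicts a central bias that scales with stimulus uncertainty.

Encoding noise can depend on orientation through an oblique-effect term: a
Gaussian bump of extra noise centred on the obliques (45/135 deg), zero at
the cardinals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .circular import distance_to_oblique, orientation_resultant, wrap_orientation
from .grid import (
    CENTER_LOCATION,
    N_LOCATIONS,
    ONSET_COLUMNS,
    ORI_COLUMNS,
)

__all__ = [
    "EnsembleDesign",
    "ObserverModel",
    "generate_ensemble",
    "simulate_response",
    "simulate_dataset",
    "write_trials",
    "read_trials",
    "exp1_design",
    "exp2_design",
    "exp3_design",
    "exp4_design",
    "uniform_observer",
    "fixed_weight_observer",
    "reliability_weighted_observer",
    "center_boost_profile",
    "linear_rank_profile",
    "quadratic_rank_profile",
]

#: Resultant length below which a circular mean is treated as degenerate.
_DEGENERATE_TOL = 1e-9

TRIAL_COLUMNS = (
    ["subject_id", "experiment_id", "trial_index", "sigma_deg", "duration_ms",
     "generating_mean_deg"]
    + ORI_COLUMNS
    + ONSET_COLUMNS
    + ["report_deg", "rt_s"]
)


@dataclass(frozen=True)
class EnsembleDesign:
    """Stimulus-side description of one experiment.

    Parameters mirror the displays used in ensemble-orientation adjustment
    experiments: a 5x5 invisible grid of Gabors (8 or 12 deg of visual angle
    per side, +/-0.25 deg position jitter), trial means drawn from a grid of
    ``mean_step_deg`` on [0, 180), element orientations scattered around the
    mean with SD ``sigma`` (one of ``sigma_levels``), and either simultaneous
    presentation at one of ``duration_levels_ms`` or jittered element onsets
    (each element visible for ``element_duration_ms`` inside a
    ``total_window_ms`` presentation window).
    """

    grid_rows: int = 5
    grid_cols: int = 5
    grid_extent_deg: float = 8.0
    position_jitter_deg: float = 0.25
    mean_step_deg: float = 10.0
    sigma_levels: tuple[float, ...] = (10.0,)
    duration_levels_ms: tuple[float, ...] = (500.0,)
    onset_policy: str = "simultaneous"
    element_duration_ms: float = 300.0
    total_window_ms: float = 800.0
    onset_frame_ms: Optional[float] = None
    n_trials_per_subject: int = 400

    def __post_init__(self):
        if self.grid_rows * self.grid_cols != N_LOCATIONS:
            raise ValueError("grid must contain exactly 25 cells")
        if self.onset_policy not in ("simultaneous", "jittered"):
            raise ValueError(f"unknown onset_policy {self.onset_policy!r}")
        if not self.sigma_levels or any(s <= 0 for s in self.sigma_levels):
            raise ValueError("sigma_levels must be positive")
        if any(d <= 0 for d in self.duration_levels_ms):
            raise ValueError("duration levels must be positive")
        if not (0 < self.mean_step_deg <= 180):
            raise ValueError("mean_step_deg must be in (0, 180]")
        if self.onset_policy == "jittered":
            if self.element_duration_ms > self.total_window_ms:
                raise ValueError("element duration exceeds the presentation window")
        if self.n_trials_per_subject < 1:
            raise ValueError("n_trials_per_subject must be >= 1")

    @property
    def onset_range_ms(self) -> float:
        """Latest admissible element onset for jittered designs."""
        return self.total_window_ms - self.element_duration_ms


def exp1_design(**overrides) -> EnsembleDesign:
    """Laboratory design: 8-deg grid, 10-deg mean steps, sigma 10, 500 ms."""
    kw = dict(grid_extent_deg=8.0, mean_step_deg=10.0, sigma_levels=(10.0,),
              duration_levels_ms=(500.0,))
    kw.update(overrides)
    return EnsembleDesign(**kw)


def exp2_design(**overrides) -> EnsembleDesign:
    """Online design with variability manipulation: sigma in {5, 10, 15}."""
    kw = dict(grid_extent_deg=8.0, mean_step_deg=1.0, sigma_levels=(5.0, 10.0, 15.0),
              duration_levels_ms=(500.0,))
    kw.update(overrides)
    return EnsembleDesign(**kw)


def exp3_design(**overrides) -> EnsembleDesign:
    """Online design with duration manipulation: 100/500/1000 ms."""
    kw = dict(grid_extent_deg=8.0, mean_step_deg=1.0, sigma_levels=(10.0,),
              duration_levels_ms=(100.0, 500.0, 1000.0))
    kw.update(overrides)
    return EnsembleDesign(**kw)


def exp4_design(**overrides) -> EnsembleDesign:
    """Sequential design: 12-deg grid, randomised onsets inside 800 ms."""
    kw = dict(grid_extent_deg=12.0, mean_step_deg=1.0, sigma_levels=(10.0,),
              duration_levels_ms=(800.0,), onset_policy="jittered",
              element_duration_ms=300.0, total_window_ms=800.0)
    kw.update(overrides)
    return EnsembleDesign(**kw)


def _default_parafoveal_noise(sigma: float, scale: float) -> float:
    return scale * sigma


@dataclass
class ObserverModel:
    """Generative response model for one simulated observer.

    Noise parameters are degrees of orientation.  ``foveal_noise_sd`` is the
    encoding noise on the central element; the parafoveal cue (average of the
    other 24) carries noise ``parafoveal_noise_fn(sigma)``, by default
    ``parafoveal_noise_scale * sigma`` so that parafoveal reliability tracks
    ensemble variability while foveal reliability does not.  Oblique-effect
    noise is an extra SD of ``amplitude * exp(-(d/width)^2)`` where ``d`` is
    the distance of the encoded orientation to the nearest oblique; the
    parafoveal amplitude is larger by default because the oblique effect is
    amplified when pooling noisy parafoveal signals.  Exposure duration
    rescales both encoding noises by ``(duration_reference_ms / duration) **
    duration_exponent`` — a common factor, so reliability ratios (and hence
    the central bias) are duration-invariant while precision is not.  The
    default exponent 0.25 is sublinear: ensemble precision improves only
    modestly with longer exposure, and mild scaling also keeps encoding noise
    inside the linear regime of the orientation circle.
    """

    kind: str = "reliability_weighted"
    weight_profile: Optional[np.ndarray] = None
    rank_weight_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    foveal_noise_sd: float = 12.0
    parafoveal_noise_scale: float = 0.6
    parafoveal_noise_fn: Optional[Callable[[float], float]] = None
    oblique_amplitude: Optional[float] = None
    foveal_oblique_amplitude: float = 0.0
    parafoveal_oblique_amplitude: float = 0.0
    oblique_width_deg: float = 15.0
    motor_noise_sd: float = 5.0
    duration_reference_ms: Optional[float] = 500.0
    duration_exponent: float = 0.25
    duration_noise_fn: Optional[Callable[[float], float]] = None
    name: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("uniform", "fixed_weights", "reliability_weighted"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if self.oblique_amplitude is not None:
            self.foveal_oblique_amplitude = float(self.oblique_amplitude)
            self.parafoveal_oblique_amplitude = float(self.oblique_amplitude)
        for name in ("foveal_noise_sd", "foveal_oblique_amplitude",
                     "parafoveal_oblique_amplitude", "motor_noise_sd",
                     "parafoveal_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.weight_profile is not None:
            w = np.asarray(self.weight_profile, dtype=float)
            if w.shape != (N_LOCATIONS,):
                raise ValueError("weight_profile must have 25 entries")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weight_profile must be nonnegative with positive sum")
            self.weight_profile = w / w.sum()

    # -- noise components -------------------------------------------------

    def parafoveal_noise(self, sigma):
        if self.parafoveal_noise_fn is not None:
            return np.asarray([self.parafoveal_noise_fn(s) for s in np.atleast_1d(sigma)])
        return self.parafoveal_noise_scale * np.asarray(sigma, dtype=float)

    def duration_factor(self, duration_ms):
        if self.duration_noise_fn is not None:
            return np.asarray([self.duration_noise_fn(d) for d in np.atleast_1d(duration_ms)])
        if self.duration_reference_ms is None:
            return np.ones_like(np.asarray(duration_ms, dtype=float))
        return (self.duration_reference_ms
                / np.asarray(duration_ms, dtype=float)) ** self.duration_exponent

    def oblique_noise(self, theta, amplitude):
        d = distance_to_oblique(theta)
        return amplitude * np.exp(-((d / self.oblique_width_deg) ** 2))


def uniform_observer(motor_noise_sd: float = 5.0, name: str | None = None) -> ObserverModel:
    return ObserverModel(kind="uniform", motor_noise_sd=motor_noise_sd, name=name)


def fixed_weight_observer(weight_profile=None, motor_noise_sd: float = 5.0,
                          rank_weight_fn=None, name: str | None = None) -> ObserverModel:
    if weight_profile is None and rank_weight_fn is None:
        weight_profile = center_boost_profile()
    return ObserverModel(kind="fixed_weights", weight_profile=weight_profile,
                         rank_weight_fn=rank_weight_fn,
                         motor_noise_sd=motor_noise_sd, name=name)


def reliability_weighted_observer(foveal_noise_sd: float = 12.0,
                                  parafoveal_noise_scale: float = 0.6,
                                  foveal_oblique_amplitude: float = 0.0,
                                  parafoveal_oblique_amplitude: float = 0.0,
                                  motor_noise_sd: float = 5.0,
                                  name: str | None = None,
                                  **kwargs) -> ObserverModel:
    return ObserverModel(kind="reliability_weighted",
                         foveal_noise_sd=foveal_noise_sd,
                         parafoveal_noise_scale=parafoveal_noise_scale,
                         foveal_oblique_amplitude=foveal_oblique_amplitude,
                         parafoveal_oblique_amplitude=parafoveal_oblique_amplitude,
                         motor_noise_sd=motor_noise_sd, name=name, **kwargs)


def center_boost_profile(boost: float = 3.0) -> np.ndarray:
    """Weight profile with the central element weighted ``boost`` times more."""
    w = np.ones(N_LOCATIONS)
    w[CENTER_LOCATION - 1] = boost
    return w / w.sum()


def linear_rank_profile(location: int = CENTER_LOCATION, base: float = 0.06,
                        slope: float = 0.012) -> Callable[[np.ndarray], np.ndarray]:
    """Rank-dependent profile whose weight at ``location`` is exactly linear
    in that element's serial rank: ``base + slope * (rank - 1)``; the other
    24 locations share the remaining weight equally."""
    idx = location - 1

    def fn(ranks: np.ndarray) -> np.ndarray:
        w_loc = base + slope * (ranks[idx] - 1)
        w = np.full(N_LOCATIONS, (1.0 - w_loc) / (N_LOCATIONS - 1))
        w[idx] = w_loc
        return w

    return fn


def quadratic_rank_profile(location: int, base: float = 0.05,
                           depth: float = 0.25) -> Callable[[np.ndarray], np.ndarray]:
    """Rank-dependent profile, U-shaped in rank (primacy + recency): weight
    ``base + depth * ((rank - 13) / 12)^2`` at ``location``."""
    idx = location - 1

    def fn(ranks: np.ndarray) -> np.ndarray:
        w_loc = base + depth * ((ranks[idx] - 13.0) / 12.0) ** 2
        w = np.full(N_LOCATIONS, (1.0 - w_loc) / (N_LOCATIONS - 1))
        w[idx] = w_loc
        return w

    return fn


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------

def _draw_means(design: EnsembleDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    steps = np.arange(0.0, 180.0, design.mean_step_deg)
    return steps[rng.integers(0, len(steps), size=n)]


def _draw_onsets(design: EnsembleDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    hi = design.onset_range_ms
    onsets = rng.uniform(0.0, hi, size=(n, N_LOCATIONS))
    if design.onset_frame_ms:
        onsets = np.round(onsets / design.onset_frame_ms) * design.onset_frame_ms
    return onsets


def generate_ensemble(design: EnsembleDesign, sigma: float, rng: np.random.Generator):
    """Draw one trial's stimuli.

    Returns ``(orientations, generating_mean, onsets)`` where orientations
    are 25 values in [0, 180): the generating mean (uniform on the
    ``mean_step_deg`` grid) plus wrapped-normal noise of SD ``sigma``.
    ``onsets`` is None for simultaneous designs.
    """
    if not np.isfinite(sigma) or sigma < 0:
        raise ValueError(f"sigma must be a nonnegative finite number, got {sigma}")
    mean = float(_draw_means(design, 1, rng)[0])
    oris = wrap_orientation(mean + rng.normal(0.0, sigma, size=N_LOCATIONS))
    onsets = None
    if design.onset_policy == "jittered":
        onsets = _draw_onsets(design, 1, rng)[0]
    return oris, mean, onsets


# ---------------------------------------------------------------------------
# Response generation
# ---------------------------------------------------------------------------

def _geodesic_combine(x_p, x_c, w_c):
    """Inverse-variance combination of two orientation cues along the
    shorter arc: move from the parafoveal cue toward the foveal cue by the
    foveal weight ``w_c``."""
    from .circular import acute_angle_diff

    return wrap_orientation(x_p + w_c * acute_angle_diff(x_c, x_p))


def _simulate_reports(oris: np.ndarray, sigma, duration_ms, observer: ObserverModel,
                      rng: np.random.Generator, ranks: np.ndarray | None = None):
    """Vectorised response generation for ``n`` trials.

    Returns ``(reports, degenerate)`` where ``degenerate`` flags trials whose
    circular mean was undefined (report then drawn uniformly).
    """
    oris = np.atleast_2d(np.asarray(oris, dtype=float))
    n = oris.shape[0]
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    duration_ms = np.broadcast_to(np.asarray(duration_ms, dtype=float), (n,))
    degenerate = np.zeros(n, dtype=bool)

    if observer.kind == "uniform":
        mean, r = orientation_resultant(oris, axis=1)
        degenerate = r < _DEGENERATE_TOL
        internal = mean
    elif observer.kind == "fixed_weights":
        if observer.rank_weight_fn is not None:
            if ranks is None:
                raise ValueError("rank-dependent observer requires element ranks")
            weights = np.stack([observer.rank_weight_fn(row) for row in np.asarray(ranks)])
        else:
            profile = observer.weight_profile
            if profile is None:
                profile = np.full(N_LOCATIONS, 1.0 / N_LOCATIONS)
            weights = np.broadcast_to(profile, oris.shape)
        mean, r = orientation_resultant(oris, axis=1, weights=weights)
        degenerate = r < _DEGENERATE_TOL
        internal = mean
    elif observer.kind == "reliability_weighted":
        center = oris[:, CENTER_LOCATION - 1]
        others = np.delete(oris, CENTER_LOCATION - 1, axis=1)
        para_mean, r = orientation_resultant(others, axis=1)
        degenerate = r < _DEGENERATE_TOL
        s = observer.duration_factor(duration_ms)
        sd_c = (observer.foveal_noise_sd
                + observer.oblique_noise(center, observer.foveal_oblique_amplitude)) * s
        sd_p = (observer.parafoveal_noise(sigma)
                + observer.oblique_noise(para_mean, observer.parafoveal_oblique_amplitude)) * s
        x_c = wrap_orientation(center + rng.normal(0.0, 1.0, n) * sd_c)
        x_p = wrap_orientation(para_mean + rng.normal(0.0, 1.0, n) * sd_p)
        var_c, var_p = sd_c ** 2, sd_p ** 2
        denom = var_c + var_p
        # equal (zero) variances: fall back to the midpoint
        w_c = np.where(denom > 0, np.divide(var_p, np.where(denom > 0, denom, 1.0)), 0.5)
        internal = _geodesic_combine(x_p, x_c, w_c)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(observer.kind)

    reports = wrap_orientation(internal + rng.normal(0.0, 1.0, n) * observer.motor_noise_sd)
    if degenerate.any():
        reports = np.where(degenerate, rng.uniform(0.0, 180.0, n), reports)
    return reports, degenerate


def simulate_response(orientations, sigma: float, observer: ObserverModel,
                      rng: np.random.Generator, duration_ms: float | None = None,
                      ranks=None) -> float:
    """Simulate one reported orientation for a single trial."""
    if duration_ms is None:
        duration_ms = observer.duration_reference_ms or 500.0
    ranks = None if ranks is None else np.atleast_2d(ranks)
    reports, _ = _simulate_reports(np.atleast_2d(orientations), sigma, duration_ms,
                                   observer, rng, ranks=ranks)
    return float(reports[0])


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

def _rank_rows(onsets: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(onsets, method="min", axis=1).astype(int)


def simulate_dataset(design: EnsembleDesign, observers: Sequence[ObserverModel],
                     rng: np.random.Generator, experiment_id: str = "sim") -> pd.DataFrame:
    """Simulate a full trial table: subjects x conditions x trials.

    Conditions (the cross of ``sigma_levels`` and ``duration_levels_ms``) are
    balanced exactly: the trial count per subject is the largest multiple of
    the number of conditions not exceeding ``n_trials_per_subject``.  Trial
    order is randomised within subject.  Deterministic given the generator
    state.
    """
    observers = list(observers)
    if not observers:
        raise ValueError("at least one observer is required")
    conditions = [(s, d) for s in design.sigma_levels for d in design.duration_levels_ms]
    n_per = design.n_trials_per_subject // len(conditions)
    if n_per < 1:
        raise ValueError("n_trials_per_subject smaller than the number of conditions")

    frames = []
    for i, obs in enumerate(observers):
        subject_id = obs.name or f"S{i + 1:02d}"
        blocks = []
        for sig, dur in conditions:
            means = _draw_means(design, n_per, rng)
            oris = wrap_orientation(means[:, None] + rng.normal(0.0, sig, (n_per, N_LOCATIONS)))
            onsets = (_draw_onsets(design, n_per, rng)
                      if design.onset_policy == "jittered" else None)
            ranks = _rank_rows(onsets) if onsets is not None else None
            reports, _ = _simulate_reports(oris, sig, dur, obs, rng, ranks=ranks)
            block = pd.DataFrame(oris, columns=ORI_COLUMNS)
            block.insert(0, "subject_id", subject_id)
            block.insert(1, "experiment_id", experiment_id)
            block.insert(2, "sigma_deg", sig)
            block.insert(3, "duration_ms", dur)
            block.insert(4, "generating_mean_deg", means)
            if onsets is not None:
                block[ONSET_COLUMNS] = onsets
            else:
                block[ONSET_COLUMNS] = np.nan
            block["report_deg"] = reports
            block["rt_s"] = rng.lognormal(mean=np.log(1.5), sigma=0.4, size=n_per)
            blocks.append(block)
        subject_df = pd.concat(blocks, ignore_index=True)
        order = rng.permutation(len(subject_df))
        subject_df = subject_df.iloc[order].reset_index(drop=True)
        subject_df.insert(2, "trial_index", np.arange(1, len(subject_df) + 1))
        frames.append(subject_df)
    df = pd.concat(frames, ignore_index=True)
    return df[TRIAL_COLUMNS]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table to CSV with the canonical column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and not c.startswith("onset")]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for c in ONSET_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df


def observer_from_config(cfg: dict) -> ObserverModel:
    """Build an ObserverModel from a plain configuration mapping (YAML)."""
    cfg = dict(cfg)
    profile = cfg.pop("weight_profile", None)
    if profile is not None:
        if isinstance(profile, dict):
            boost = float(profile.get("center_boost", 3.0))
            profile = center_boost_profile(boost)
        else:
            profile = np.asarray(profile, dtype=float)
    rank_fn = None
    rank_cfg = cfg.pop("rank_weighting", None)
    if rank_cfg is not None:
        shape = rank_cfg.get("shape", "linear")
        loc = int(rank_cfg.get("location", CENTER_LOCATION))
        if shape == "linear":
            rank_fn = linear_rank_profile(loc, base=rank_cfg.get("base", 0.06),
                                          slope=rank_cfg.get("slope", 0.006))
        elif shape == "quadratic":
            rank_fn = quadratic_rank_profile(loc, base=rank_cfg.get("base", 0.05),
                                             depth=rank_cfg.get("depth", 0.12))
        else:
            raise ValueError(f"unknown rank_weighting shape {shape!r}")
    return ObserverModel(weight_profile=profile, rank_weight_fn=rank_fn, **cfg)


def design_from_config(cfg: dict) -> EnsembleDesign:
    """Build an EnsembleDesign from a plain configuration mapping (YAML)."""
    cfg = dict(cfg)
    for key in ("sigma_levels", "duration_levels_ms"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return EnsembleDesign(**cfg)
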