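"""End-to-end runs: simulate/load -> preprocess -> SWM -> inference -> report.

A run is described by a :class:`RunConfig` (usually a YAML file): either an
input trial-table CSV or a simulation block, an experiment kind selecting
the analysis sequence, outlier rules, analysis switches, a mandatory seed
and an output directory.  Every stochastic stage draws from its own
substream of the run seed, so toggling one stage never shifts another's
randomness, and a re-run with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grid import CENTER_LOCATION
from .group import condition_effect_map, permutation_location_test
from .model import fit_subject_maps, response_stimulus_distance
from .oblique import bias_slope_test, central_distance_binning, sliding_window_bias
from .preprocess import OutlierRules, preprocess
from .simulate import design_from_config, observer_from_config, read_trials, \
    simulate_dataset, write_trials
from .temporal import add_serial_ranks, aggregate_and_zscore, \
    cross_condition_prediction, serial_swm_matrix, serial_timecourse_cv

logger = logging.getLogger("swmap")

EXPERIMENT_KINDS = ("exp1", "exp2", "exp3", "exp4")

# fixed substream indices per stage, so stages are independently seeded
_STAGE_STREAMS = {"simulate": 0, "group": 1, "conditions": 2, "oblique": 3,
                  "temporal": 4, "cross": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage of a seeded run."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(_STAGE_STREAMS[stage],)))


@dataclass
class RunConfig:
    experiment_kind: str = "exp1"
    input: str | None = None
    simulation: dict | None = None
    outlier_rules: dict = field(default_factory=dict)
    reference: str = "sample_mean"
    n_permutations: int = 10_000
    alpha: float = 0.05
    window_width: float = 20.0
    window_step: float = 5.0
    n_cv_splits: int = 10_000
    cv_folds: int = 5
    n_shuffles: int = 200
    seed: int | None = None
    output_dir: str = "swmap_output"

    def __post_init__(self):
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise ValueError(f"experiment_kind must be one of {EXPERIMENT_KINDS}")
        if (self.input is None) == (self.simulation is None):
            raise ValueError("exactly one of 'input' and 'simulation' must be given")
        if self.seed is None:
            raise ValueError("a seed is mandatory: permutation tests, simulation "
                             "and cross-validation are all stochastic")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


@dataclass
class RunReport:
    seed: int
    experiment_kind: str
    version: str
    artifacts: dict = field(default_factory=dict)   # name -> {path, sha256}
    removal_log: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run(config: RunConfig) -> RunReport:
    """Execute the stage sequence for ``config.experiment_kind``.

    Writes the preprocessed table, per-subject weight maps, group maps and
    the experiment-specific analyses into ``config.output_dir``, plus a
    ``report.json`` manifest listing every artifact with its checksum.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, experiment_kind=config.experiment_kind,
                       version=__version__)

    def register(name: str, path: Path):
        report.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    # --- stage: obtain trials ------------------------------------------------
    if config.simulation is not None:
        logger.info("simulating dataset (%s)", config.experiment_kind)
        sim = dict(config.simulation)
        design = design_from_config(sim.get("design", {}))
        observers = [observer_from_config(o) for o in sim.get("observers", [])]
        if not observers:
            raise ValueError("simulation block must list at least one observer")
        trials = simulate_dataset(design, observers, stage_rng(config.seed, "simulate"),
                                  experiment_id=config.experiment_kind)
        trials_path = out / "trials.csv"
        write_trials(trials, trials_path)
        register("trials", trials_path)
    else:
        trials = read_trials(config.input)

    # --- stage: preprocess ---------------------------------------------------
    rules = OutlierRules(**config.outlier_rules)
    pre, log = preprocess(trials, rules, reference=config.reference)
    pre_path = out / "preprocessed.csv"
    pre.to_csv(pre_path, index=False)
    register("preprocessed", pre_path)
    log_path = out / "removal_log.json"
    log.to_json(log_path)
    register("removal_log", log_path)
    report.removal_log = json.loads(log.to_json())

    # --- stage: per-subject SWMs + group test --------------------------------
    maps = fit_subject_maps(pre)
    _write_json({s: r.to_dict() for s, r in maps.items()}, out / "subject_weights.json")
    register("subject_weights", out / "subject_weights.json")
    group = permutation_location_test(maps, n_permutations=config.n_permutations,
                                      alpha=config.alpha,
                                      rng=stage_rng(config.seed, "group"))
    _write_json(group.to_dict(), out / "group_map.json")
    register("group_map", out / "group_map.json")
    dist = response_stimulus_distance(pre)
    _write_json({"distances": dist.tolist()}, out / "response_stimulus_distance.json")
    register("response_stimulus_distance", out / "response_stimulus_distance.json")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .plotting import plot_weight_heatmap

    ax = plot_weight_heatmap(group.mean_t, significant=group.significant,
                             title="group weight map (t)")
    ax.figure.savefig(out / "group_map.png", dpi=120)
    plt.close(ax.figure)
    register("group_map_png", out / "group_map.png")

    # --- experiment-specific stages ------------------------------------------
    if config.experiment_kind == "exp1":
        curve = sliding_window_bias(pre, window_width=config.window_width,
                                    step=config.window_step)
        curve.to_frame().to_csv(out / "bias_curve.csv", index=False)
        register("bias_curve", out / "bias_curve.csv")
        slope = bias_slope_test(curve)
        _write_json({"mean_slope": slope.mean_slope, "t": slope.t, "p": slope.p,
                     "d_prime": slope.d_prime}, out / "bias_slope.json")
        register("bias_slope", out / "bias_slope.json")
        try:
            bins = central_distance_binning(pre)
            bins.to_frame().to_csv(out / "distance_bins.csv", index=False)
            register("distance_bins", out / "distance_bins.csv")
        except ValueError as exc:
            logger.warning("distance binning skipped: %s", exc)
    elif config.experiment_kind in ("exp2", "exp3"):
        col = "sigma_deg" if config.experiment_kind == "exp2" else "duration_ms"
        cond_maps = fit_subject_maps(pre, condition_col=col)
        levels = sorted(pre[col].unique())
        effect = condition_effect_map(cond_maps, levels,
                                      n_permutations=config.n_permutations,
                                      alpha=config.alpha,
                                      rng=stage_rng(config.seed, "conditions"))
        _write_json(effect.to_dict(), out / "condition_effect_map.json")
        register("condition_effect_map", out / "condition_effect_map.json")
        if config.experiment_kind == "exp3":
            cross = cross_condition_prediction(pre, col, train_level=min(levels),
                                               k=config.cv_folds,
                                               rng=stage_rng(config.seed, "cross"),
                                               n_shuffles=config.n_shuffles)
            cross.per_subject.to_csv(out / "cross_condition.csv", index=False)
            register("cross_condition", out / "cross_condition.csv")
    elif config.experiment_kind == "exp4":
        pooled, dropped = aggregate_and_zscore(add_serial_ranks(pre))
        if dropped:
            logger.warning("subjects dropped from pooling: %s", dropped)
        mat = serial_swm_matrix(pooled)
        mat.to_frame().to_csv(out / "serial_weight_matrix.csv")
        register("serial_weight_matrix", out / "serial_weight_matrix.csv")
        cv = serial_timecourse_cv(pooled, CENTER_LOCATION,
                                  n_splits=config.n_cv_splits,
                                  rng=stage_rng(config.seed, "temporal"))
        _write_json(cv.to_dict(), out / "central_timecourse_cv.json")
        register("central_timecourse_cv", out / "central_timecourse_cv.json")

    report_path = out / "report.json"
    report.to_json(report_path)
    return report
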