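import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from swmap.grid import ONSET_COLUMNS, ORI_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trials(rows):
    """Build a minimal trial table from dicts with keys:
    subject, oris (25), report, rt (optional), mean (optional)."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "subject_id": row.get("subject", "S1"),
            "experiment_id": "test",
            "trial_index": i + 1,
            "sigma_deg": 10.0,
            "duration_ms": 500.0,
            "generating_mean_deg": row.get("mean", 90.0),
            "report_deg": row["report"],
            "rt_s": row.get("rt", 1.0),
        }
        oris = np.asarray(row["oris"], dtype=float)
        rec.update(dict(zip(ORI_COLUMNS, oris)))
        rec.update({c: row.get("onsets", [np.nan] * 25)[k]
                    for k, c in enumerate(ONSET_COLUMNS)})
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def center_weighted_exp1():
    """A small preprocessed dataset from strongly center-weighted observers,
    shared by the weight-map / distance-map mirror tests."""
    from swmap import fixed_weight_observer, preprocess, simulate_dataset
    from swmap.simulate import EnsembleDesign, center_boost_profile

    rng = np.random.default_rng(2301)
    design = EnsembleDesign(mean_step_deg=1.0, sigma_levels=(15.0,),
                            n_trials_per_subject=300)
    observers = [
        fixed_weight_observer(weight_profile=center_boost_profile(6.0),
                              motor_noise_sd=6.0, name=f"S{i:02d}")
        for i in range(8)
    ]
    df = simulate_dataset(design, observers, rng)
    pre, _ = preprocess(df)
    return pre
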