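import warnings

import numpy as np
import pandas as pd
import pytest

from foxrange.pipeline import PipelineConfig, run_synthetic_study
from foxrange.simulate import GeneratorConfig
from foxrange.trajectory import Trajectory


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trajectory(xy, start="2015-01-01", hours_step=8, animal_id="fox", **attrs):
    """Build a Trajectory from an (n, 2) array with evenly spaced timestamps."""
    xy = np.asarray(xy, dtype=float)
    ts = pd.Timestamp(start, tz="UTC") + pd.to_timedelta(
        np.arange(len(xy)) * hours_step, unit="h"
    )
    fixes = pd.DataFrame(
        {
            "timestamp": ts,
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "lon": xy[:, 0] / 111320.0,
            "lat": 58.0 + xy[:, 1] / 111320.0,
        }
    )
    return Trajectory(
        animal_id=animal_id,
        sex=attrs.get("sex", "F"),
        age_class=attrs.get("age_class", "adult"),
        study_area=attrs.get("study_area", "BN"),
        fixes=fixes,
    )


@pytest.fixture(scope="session")
def default_study_result():
    """One full default synthetic study pushed through the whole pipeline.

    Session-scoped because home-range estimation for 52 foxes takes tens of
    seconds; several end-to-end tests share it.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, truth = run_synthetic_study(
            GeneratorConfig(seed=1), pipeline_config=PipelineConfig(seed=1)
        )
    return result, truth
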