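import numpy as np
import pandas as pd
import pytest

from heatmem import (AssayNoise, LabProtocol, ModelParams, ObservationParams,
                     ObservedTimeCourse, build_lab_profile, gen_timecourse)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def obs_params():
    return ObservationParams()


@pytest.fixture(scope="session")
def lab_acc_hs():
    return build_lab_profile(LabProtocol())


@pytest.fixture(scope="session")
def lab_hs_only():
    return build_lab_profile(LabProtocol(acc_enabled=False))


@pytest.fixture(scope="session")
def constant_profile():
    return build_lab_profile(
        LabProtocol(acc_enabled=False, hs_enabled=False, total_duration=200.0))


#: sampling times mirroring the assay design: before/after ACC, the memory
#: phase, and 0/4/24 h after HS
SAMPLE_TIMES = (95.0, 96.5, 100.0, 120.0, 168.0, 173.0, 193.0)


def make_joint_timecourse(profile, seed, params=None, noise=None,
                          obs=None, assays=("expr", "K27")):
    """Synthetic WT + mutant time course split into per-genotype tables."""
    params = params or ModelParams()
    noise = noise or AssayNoise()
    obs = obs or ObservationParams()
    tc, truth = gen_timecourse(params, obs, profile, ["WT", "jmjq"],
                               SAMPLE_TIMES, noise, seed=seed, assays=assays,
                               condition="+ACC+HS")
    wt = ObservedTimeCourse(tc.data[tc.data["genotype"] == "WT"],
                            condition=tc.condition)
    jm = ObservedTimeCourse(tc.data[tc.data["genotype"] == "jmjq"],
                            condition=tc.condition)
    return wt, jm, truth
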