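import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from sst_ersp import cluster as cl
from sst_ersp import spectral as sp
from sst_ersp import synth as sy
from sst_ersp import task as tk


@pytest.fixture(scope="session")
def task_cfg() -> tk.TaskConfig:
    return tk.TaskConfig()


@pytest.fixture(scope="session")
def subject() -> tk.SubjectModel:
    return tk.SubjectModel()


@pytest.fixture(scope="session")
def session_trials(task_cfg, subject):
    """One full simulated session (practice + 160 main trials)."""
    return tk.run_session(task_cfg, subject, seed=42)


@pytest.fixture(scope="session")
def small_family() -> sp.WaveletFamily:
    """Reduced wavelet family for fast spectral tests."""
    return sp.build_wavelets(fmin=8.0, fmax=30.0, df=1.0, fs=500.0)


@pytest.fixture(scope="session")
def full_family() -> sp.WaveletFamily:
    return sp.build_wavelets()


def random_master(rng, shape=(6, 8), n_a=10, n_b=10) -> cl.MasterArray:
    power = rng.standard_normal((*shape, n_a + n_b))
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    return cl.MasterArray(power, labels, np.arange(shape[0], dtype=float),
                          np.arange(shape[1], dtype=float), groups=("A", "B"))
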