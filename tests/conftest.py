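import numpy as np
import pandas as pd
import pytest

from lfapp.hydrodynamics import CellGeometry, HydroSpecies, lamm_simulate
from lfapp.transcriptomics import CountMatrix, SampleMetadata


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()  # 6-7.25 cm at 50,000 rpm


@pytest.fixture(scope="session")
def scan_times():
    # scans every 7 min, as acquired in the experiment being modelled
    return [420.0 * (k + 1) for k in range(6)]


@pytest.fixture(scope="session")
def single_species_scans(geometry, scan_times):
    sp = HydroSpecies(label="x", s=5.1, frictional_ratio=1.38, loading_signal=0.5)
    return lamm_simulate([sp], geometry, scan_times, n_radial=300)


def nb_counts(rng, base, disp, n):
    """NB counts (genes x samples) at constant per-gene mean and dispersion."""
    mu = np.tile(np.asarray(base, dtype=float)[:, None], (1, n))
    r = 1.0 / np.asarray(disp, dtype=float)[:, None]
    return rng.negative_binomial(r, r / (r + mu))


@pytest.fixture()
def small_cohort():
    """40-sample null cohort with full covariate metadata."""
    rng = np.random.default_rng(11)
    g, n = 300, 40
    base = np.exp(rng.normal(5, 1.5, g))
    counts = nb_counts(rng, base, np.full(g, 0.1), n)
    cm = CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(g)],
                                  columns=[f"s{j}" for j in range(n)]))
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(n)],
        "group": ["case"] * 20 + ["control"] * 20,
        "batch": ["b1", "b2"] * 20,
        "age": rng.normal(85, 6, n),
        "sex": rng.choice(["m", "f"], n),
        "rin": rng.normal(7, 1, n),
        "study": rng.choice(["ROS", "MAP"], n),
    }))
    return cm, meta
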