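"""Shared fixtures.

Expensive Monte Carlo artifacts are session-scoped so the forward database
and inverse model are built once and reused; fast unit tests use a
noiseless diffusion-theory forward table instead of Monte Carlo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from skindrs.inverse import ReflectanceDatabase
from skindrs.optics import ProbeGeometry, diffusion_reflectance
from skindrs.spectral import load_water_reference


@pytest.fixture(scope="session")
def probe() -> ProbeGeometry:
    return ProbeGeometry()


@pytest.fixture(scope="session")
def water_ref():
    return load_water_reference()


def make_diffusion_database(mu_a_values, mu_sp_values) -> ReflectanceDatabase:
    """Noiseless forward table from the diffusion closed form (fast stand-in
    for the Monte Carlo database in unit tests)."""
    rows = []
    for msp in mu_sp_values:
        r = diffusion_reflectance(0.0, msp, np.array([1.0, 2.0]))
        for ma in mu_a_values:
            r = diffusion_reflectance(ma, msp, np.array([1.0, 2.0]))
            rows.append((float(ma), float(msp), r[0], r[1], 0.0, 0.0))
    table = pd.DataFrame(rows, columns=["mu_a", "mu_sp", "R1", "R2",
                                        "se1", "se2"])
    return ReflectanceDatabase(table=table, provenance={"kind": "diffusion"})


@pytest.fixture(scope="session")
def diffusion_db() -> ReflectanceDatabase:
    mu_a = np.round(np.geomspace(0.002, 1.0, 28), 6)
    mu_sp = np.round(np.linspace(0.1, 3.0, 25), 6)
    return make_diffusion_database(mu_a, mu_sp)
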