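"""Shared fixtures: synthetic inputs and one full pipeline run per session."""

from __future__ import annotations

import numpy as np
import pytest

import pulsead as pa
from pulsead.config import default_targets
from pulsead.tuning import TuneOptions, tune_pipeline


@pytest.fixture(scope="session")
def inflow():
    return pa.synth_inflow()


@pytest.fixture(scope="session")
def targets():
    return default_targets()


@pytest.fixture(scope="session")
def pipeline(inflow, targets):
    """Full 4-step tuning + rigid and compliant runs on the default fixture.

    Expensive (~30 s); shared by the integration and acceptance tests.
    Returns (geometry, report).
    """
    geom = pa.idealized_dissected_aorta()
    report = tune_pipeline(geom, inflow, targets, TuneOptions())
    return geom, report


@pytest.fixture()
def uniform_tube():
    """Single compliant tube factory: (length, n_nodes, D) -> geometry."""

    def make(length=1.0, n_nodes=101, D=1.18e-5, A0=8.042e-4, wk3=None):
        from pulsead.network import BoundaryCondition, NetworkGeometry, VesselSegment1D
        from pulsead.windkessel import WK3Params

        seg = VesselSegment1D(
            "tube", length=length, n_nodes=n_nodes, A0=A0, C_A=D * A0,
            p_ext=76.0 * 133.322,
        )
        wk3 = wk3 or WK3Params(R1=0.1, R2=3.6, C=0.15)
        return NetworkGeometry(
            [seg],
            [],
            [
                BoundaryCondition("inflow", "tube", "prox"),
                BoundaryCondition("wk3", "tube", "dist", wk3=wk3),
            ],
        )

    return make
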