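"""Shared fixtures.

The closed-loop simulations are expensive, so every protocol run used by
more than one test is computed once per session (lazily, on first use).
All runs are deterministic given their configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurohex import gait_analysis, protocols
from neurohex.params import default_params


def _forward(velocity, duration, **kw):
    cfg = protocols.ExperimentConfig(
        protocol="forward", velocity_mV=velocity, duration_s=duration, **kw
    )
    return protocols.run_protocol(cfg)


@pytest.fixture(scope="session")
def forward50():
    return _forward(50.0, 80.0)


@pytest.fixture(scope="session")
def forward20():
    return _forward(20.0, 80.0)


@pytest.fixture(scope="session")
def forward8():
    return _forward(8.0, 300.0)


@pytest.fixture(scope="session")
def forward15():
    return _forward(15.0, 80.0)


@pytest.fixture(scope="session")
def forward15_disturbed():
    cfg = protocols.ExperimentConfig(
        protocol="forward", velocity_mV=15.0, duration_s=80.0
    )
    cfg = protocols.schedule_disturbance(cfg, "MR", 15.0, 17.0)
    return protocols.run_protocol(cfg)


@pytest.fixture(scope="session")
def pilo_all():
    cfg = protocols.ExperimentConfig(duration_s=60.0)
    cfg = protocols.configure_pilocarpine(cfg, {"pro", "meso", "meta"})
    return protocols.run_protocol(cfg)


def _pilo(ganglia, duration=90.0):
    cfg = protocols.ExperimentConfig(duration_s=duration)
    cfg = protocols.configure_pilocarpine(cfg, set(ganglia))
    return protocols.run_protocol(cfg)


@pytest.fixture(scope="session")
def pilo_pro():
    return _pilo({"pro"})


@pytest.fixture(scope="session")
def pilo_meso():
    return _pilo({"meso"})


@pytest.fixture(scope="session")
def pilo_meta():
    return _pilo({"meta"})


@pytest.fixture(scope="session")
def treadmill30():
    cfg = protocols.ExperimentConfig(duration_s=60.0)
    cfg = protocols.configure_treadmill_single_leg(cfg, "FL", 30.0)
    return protocols.run_protocol(cfg)


@pytest.fixture(scope="session")
def curve_run():
    cfg = protocols.ExperimentConfig(protocol="curve", duration_s=100.0)
    cfg.curve = protocols.CurveParams()
    cfg.velocity_mV = cfg.curve.global_velocity
    return protocols.run_protocol(cfg)


@pytest.fixture(scope="session")
def backward_runs():
    out = {}
    for vel in (50.0, 20.0):
        cfg = protocols.ExperimentConfig(
            protocol="backward", velocity_mV=vel, duration_s=70.0
        )
        out[vel] = protocols.run_protocol(cfg)
    return out


@pytest.fixture(scope="session")
def stop_run():
    cfg = protocols.ExperimentConfig(
        protocol="forward", velocity_mV=30.0, duration_s=40.0,
        velocity_schedule=[(25.0, 0.0)],
    )
    return protocols.run_protocol(cfg)


def mn_onsets(trace, lid, channel="ret", frac=0.5, window=None):
    """Half-maximum burst onsets of an MN channel (helper for tests)."""
    tr = trace
    if window is not None:
        tr = tr[(tr["time_s"] >= window[0]) & (tr["time_s"] < window[1])]
    x = tr[f"{lid}_mn_{channel}"].to_numpy()
    t = tr["time_s"].to_numpy()
    thr = max(0.5, frac * x.max())
    idx = np.flatnonzero((x[:-1] <= thr) & (x[1:] > thr)) + 1
    return t[idx]


def swing_onsets(trace, lid, window=None):
    tr = trace
    if window is not None:
        tr = tr[(tr["time_s"] >= window[0]) & (tr["time_s"] < window[1])]
    x = tr[f"{lid}_swing"].to_numpy()
    t = tr["time_s"].to_numpy()
    idx = np.flatnonzero((x[:-1] < 0.5) & (x[1:] > 0.5)) + 1
    return t[idx]
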