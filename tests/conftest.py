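"""Shared fixtures: the reference model and the expensive protocol runs.

The closed-loop tilt simulations are session-scoped so the steady-state,
transient and acceptance tests share them instead of re-running the solver.
"""
import numpy as np
import pytest

from orthosim.network import load_default
from orthosim.tilt import TiltSchedule
from orthosim.engine.runner import run_protocol
from orthosim.analysis import beat_metrics, steady_window

PROTO = dict(pre_tilt_max_s=60.0, pre_tilt_min_s=40.0,
             post_tilt_max_s=120.0, steady_tol=5e-4)


@pytest.fixture(scope="session")
def model():
    return load_default()


def _tilt_run(model, a0, a1, rate, regulation=True, targets=None, **kw):
    sched = TiltSchedule(alpha_start=a0, alpha_end=a1, mean_rate=rate)
    opts = dict(PROTO)
    opts.update(kw)
    return run_protocol(model, sched, regulation=regulation,
                        targets=targets, **opts)


@pytest.fixture(scope="session")
def hut70_record(model):
    """Supine steady state + 70 degree head-up tilt at 4 deg/s."""
    return _tilt_run(model, 0, 70, 4.0)


@pytest.fixture(scope="session")
def hut70_windows(hut70_record):
    m = beat_metrics(hut70_record)
    sup = steady_window(m, t_end=hut70_record.phases["pre_tilt_end"])
    til = steady_window(m)
    return m, sup, til


@pytest.fixture(scope="session")
def rate_sweep_records(model, hut70_record):
    """HUT to 70 degrees at three tilting rates (35, 4, 1.4 deg/s)."""
    return {35.0: _tilt_run(model, 0, 70, 35.0),
            4.0: hut70_record,
            1.4: _tilt_run(model, 0, 70, 1.4)}


@pytest.fixture(scope="session")
def tilt_down_record(model, hut70_record):
    """Tilt-down from 70 degrees to supine at 1.4 deg/s, with the
    regulation set points captured in the supine state of the tilt-up
    run (the paper-style protocol returns the same subject)."""
    return _tilt_run(model, 70, 0, 1.4, post_tilt_max_s=180.0,
                     targets=hut70_record.meta["targets"])


@pytest.fixture(scope="session")
def regulation_off_record(model):
    return _tilt_run(model, 0, 70, 4.0, regulation=False)


def rel_change(sup, til, key):
    return 100.0 * (til[key] - sup[key]) / sup[key]


def transient_window(record, metrics, tail_s=30.0):
    return metrics[(metrics.t > record.phases["ramp_start"])
                   & (metrics.t < record.phases["ramp_end"] + tail_s)]
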