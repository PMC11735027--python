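"""Shared fixtures: small seeded simulations reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import timeddm as tdm


@pytest.fixture(scope="session")
def d2_run() -> tdm.DDMRun:
    """One 500-trial intact-D2 batch."""
    return tdm.simulate_batch(tdm.INTACT_D2.with_seed(11))


@pytest.fixture(scope="session")
def d2_run_traj() -> tdm.DDMRun:
    """Intact-D2 batch with stored trajectories for ensemble linking."""
    params = dataclasses.replace(tdm.INTACT_D2, n_sims=160, seed=21,
                                 store_trajectories=True)
    return tdm.simulate_batch(params)


@pytest.fixture(scope="session")
def linked_ensemble(d2_run_traj) -> tdm.EnsembleData:
    """Default 16-unit, 40-trial DDM-linked ensemble."""
    return tdm.gen_ensemble_ddm_linked(tdm.SynthEnsembleSpec(seed=21),
                                       d2_run_traj)


@pytest.fixture(scope="session")
def readout_fit(linked_ensemble) -> tdm.EnsembleReadout:
    return tdm.fit_readout(linked_ensemble)


@pytest.fixture(scope="session")
def behavior_events():
    spec = tdm.SynthBehaviorSpec(n_trials=80, seed=3)
    times = tdm.gen_switch_times(spec)
    return spec, times, tdm.gen_event_log(spec, times)


def ramping_counts(slopes, n_trials, config, baseline=8.0, seed=0):
    """Poisson counts on the decoder bin grid for ramp-then-hold units.

    Rate is baseline + slope * clip(t, 0, 6): a linear ramp over the
    0-6 s interval that holds its final level afterwards, so ensemble
    signatures are unique (hence decodable) only while units ramp.  A
    quick generator for decoder tests that bypasses spike-level
    thinning.
    """
    rng = np.random.default_rng(seed)
    centers = config.bin_centers
    ramped = np.clip(centers, 0.0, 6.0)
    rates = np.maximum(0.0, baseline
                       + np.asarray(slopes)[:, None] * ramped[None, :])
    lam = rates[None] * config.bin_width_s
    return rng.poisson(np.broadcast_to(lam, (n_trials,) + rates.shape))
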