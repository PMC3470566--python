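"""Shared fixtures.

The expensive high-frequency-stimulation (HFS) simulations are run once
per session and shared by the protocol and acceptance tests.
"""

import numpy as np
import pytest

from ionshift import calibration, morphology, params, protocols, solver

HFS_KW = dict(duration=1600.0, na_blocked=True, activation=0.8)


@pytest.fixture(scope="session")
def default_params():
    return params.default_params()


@pytest.fixture(scope="session")
def bas_model():
    """Ball-and-stick: soma plus a thin 400 um apical stick."""
    return morphology.make_fixture("ball_and_stick")


@pytest.fixture(scope="session")
def bas_membrane(bas_model, default_params):
    membrane = solver.build_membrane(bas_model, default_params)
    calibration.balance_rest(bas_model, membrane)
    return membrane


@pytest.fixture(scope="session")
def branched_model():
    """Reduced CA1-like tree with mixed radii and all density classes."""
    return morphology.make_fixture("branched")


@pytest.fixture(scope="session")
def branched_membrane(branched_model, default_params):
    membrane = solver.build_membrane(branched_model, default_params)
    calibration.balance_rest(branched_model, membrane)
    return membrane


def passive_membrane(model, p, g_leak_k=1e-4):
    """A membrane with only a potassium leak (frozen-concentration RC cell)."""
    membrane = solver.build_membrane(model, p)
    membrane.gna_bar = np.zeros(model.n)
    for name in list(membrane.hh_channels):
        channel, gbar = membrane.hh_channels[name]
        membrane.hh_channels[name] = (channel, np.zeros(model.n))
    membrane.gaba_gmax = np.zeros(model.n)
    membrane.kcc2_vmax = np.zeros(model.n)
    membrane.capump_imax = np.zeros(model.n)
    membrane.g_leak_ca = np.zeros(model.n)
    membrane.g_leak_k = np.full(model.n, g_leak_k)
    membrane.calibrated = True
    return membrane


@pytest.fixture(scope="session")
def kcc2_recovery(bas_model, bas_membrane):
    """Round-trip recovery of the KCC2 transport density from a
    model-generated chloride-clearance curve (shared: the fit is the
    expensive part)."""
    comp = int(np.argmin(np.abs(bas_model.path_distance - 200.0)))
    true_vmax = float(bas_membrane.kcc2_vmax[comp])
    t, cl = calibration.simulate_clearance(bas_model, bas_membrane,
                                           true_vmax, comp, duration_ms=500.0)
    fitted = calibration.fit_kcc2_density(t, cl, bas_model, bas_membrane,
                                          comp, bounds=(1e-3, 0.1))
    return {"comp": comp, "true_vmax": true_vmax, "fitted": fitted,
            "time": t, "cl": cl}


@pytest.fixture(scope="session")
def hfs_control(bas_model, bas_membrane):
    """Control HFS run (80% activation, fast Na blocked)."""
    return protocols.run_hfs(bas_model, bas_membrane, **HFS_KW)


@pytest.fixture(scope="session")
def hfs_gaba_inhibited(bas_model, bas_membrane):
    """HFS with 60% of GABA_A receptors blocked (quinine mode)."""
    return protocols.run_intervention(bas_model, bas_membrane,
                                      {"gaba_inhibition": 0.6}, **HFS_KW)


@pytest.fixture(scope="session")
def hfs_kcc2_inhibited(bas_model, bas_membrane):
    """HFS with 60% of KCC2 transport blocked."""
    return protocols.run_intervention(bas_model, bas_membrane,
                                      {"kcc2_inhibition": 0.6}, **HFS_KW)
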