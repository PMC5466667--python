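"""Shared fixtures: models, physics blocks, and an SSA-scale settled protocell."""

from __future__ import annotations

from dataclasses import replace

import pytest

from protocell import build_pm1, build_pm2
from protocell.experiments import _reproducing_setup, settle_reproducing
from protocell.physics import PhysicsParams


@pytest.fixture(scope="session")
def pm1_model():
    return build_pm1()


@pytest.fixture(scope="session")
def pm2_model():
    return build_pm2()


@pytest.fixture()
def physics():
    return PhysicsParams()


@pytest.fixture(scope="session")
def ssa_settled():
    """PM2 protocell settled onto its division attractor at SSA desk scale.

    Boosted lipid synthesis keeps the stationary cell small enough that a
    stochastic division costs only a few million events.  Returns
    (model, physics, concentrations) positioned just below the division
    threshold so seeded runs divide almost immediately.
    """
    overrides = {"k_syn": 0.25}
    model, physics, scen = _reproducing_setup("pm2", 0.02, overrides)
    conc, settled, traj = settle_reproducing(model, physics, scen["init_conc"])
    assert conc is not None, f"settle failed: {traj.outcome}"
    physics2 = replace(
        physics, chi0=settled["chi"], phi0=1.25, r0=settled["r_nm"]
    )
    return model, physics2, conc
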